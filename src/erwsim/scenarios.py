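"""Packaged experiment scenarios.

``mesocosm_sorghum``: a 121-day controlled sorghum mesocosm with a crushed
basalt assemblage and F_D = 0.5.  ``illinois_maize_soy`` (and its
``_xrd`` mineralogy variant): four annual 5 kg m-2 basalt
applications to a 30 cm layer under a maize-soybean rotation with F_D = 1;
site forcing must be supplied by the user (or synthesised).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .config import SimulationConfig, validate_config
from .errors import ConfigError

SCENARIOS = ("mesocosm_sorghum", "illinois_maize_soy", "illinois_maize_soy_xrd")


def scenario_config(name: str) -> SimulationConfig:
    """Load and validate one of the packaged scenario configurations."""
    if name not in SCENARIOS:
        raise ConfigError(f"unknown scenario {name!r}; available: {SCENARIOS}")
    src = resources.files("erwsim.data").joinpath(f"{name}.yaml")
    with resources.as_file(src) as path:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return validate_config(raw)
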