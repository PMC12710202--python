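"""Mineral dissolution-kinetics library.

Entries follow the acid/neutral/base multi-mechanism rate-law compilation
of Palandri and Kharaka (USGS Open-File Report 2004-1068): per mechanism a
log10 rate constant at 25 degC (mol m-2 s-1), an Arrhenius activation
energy (kJ mol-1) and an H+ reaction order.  The packaged table
(`data/minerals.csv`) carries a source tag per row; ferroactinolite is
proxied by tremolite (amphibole endmember) kinetics for lack of a
dedicated entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .constants import R_GAS, T_REF_K
from .errors import ConfigError

ELEMENTS = ("Ca", "Mg", "K", "Na", "Si", "Al", "P", "C")


@dataclass(frozen=True)
class Mechanism:
    name: str          # acid / neutral / base
    log_k25: float     # mol m-2 s-1
    ea_kj: float       # kJ mol-1
    n_h: float         # H+ reaction order (>=0 acid, 0 neutral, <=0 base)


@dataclass
class MineralKinetics:
    name: str
    molar_mass: float                      # g mol-1
    stoichiometry: dict[str, float]        # mol element per mol mineral
    mechanisms: list[Mechanism] = field(default_factory=list)
    log_keq: float | None = None           # solubility product, if tracked

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ConfigError(f"{self.name}: molar mass must be > 0")
        if any(v < 0 for v in self.stoichiometry.values()):
            raise ConfigError(f"{self.name}: negative stoichiometric coefficient")
        for m in self.mechanisms:
            if m.name == "acid" and m.n_h < 0:
                raise ConfigError(f"{self.name}: acid mechanism needs n_H >= 0")
            if m.name == "base" and m.n_h > 0:
                raise ConfigError(f"{self.name}: base mechanism needs n_H <= 0")

    def rate_constant(self, temp_c: float, h_activity: float) -> float:
        """Sum of mechanism rates k_m(T) * (a_H+)^n_m, mol m-2 s-1."""
        t_k = temp_c + 273.15
        total = 0.0
        for m in self.mechanisms:
            arrh = math.exp(-(m.ea_kj * 1000.0 / R_GAS) * (1.0 / t_k - 1.0 / T_REF_K))
            total += 10.0 ** m.log_k25 * arrh * h_activity ** m.n_h
        return total


def load_mineral_library(path=None) -> dict[str, MineralKinetics]:
    """Load the mineral library (packaged table by default).

    The file dialect is delimited text with one row per mineral-mechanism:
    ``mineral,mechanism,log_k25,Ea_kJmol,n_H,molar_mass_g,stoich_*,log_Keq``.
    """
    if path is None:
        src = resources.files("erwsim.data").joinpath("minerals.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)

    library: dict[str, MineralKinetics] = {}
    for name, grp in df.groupby("mineral", sort=False):
        first = grp.iloc[0]
        stoich = {
            el: float(first[f"stoich_{el}"])
            for el in ELEMENTS
            if float(first[f"stoich_{el}"]) > 0
        }
        log_keq = first["log_Keq"]
        mins = MineralKinetics(
            name=str(name),
            molar_mass=float(first["molar_mass_g"]),
            stoichiometry=stoich,
            mechanisms=[
                Mechanism(
                    str(r["mechanism"]),
                    float(r["log_k25"]),
                    float(r["Ea_kJmol"]),
                    float(r["n_H"]),
                )
                for _, r in grp.iterrows()
            ],
            log_keq=None if pd.isna(log_keq) else float(log_keq),
        )
        library[mins.name] = mins
    return library
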