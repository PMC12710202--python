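"""Simulation configuration: schema, defaults, validation.

Configuration documents are hierarchical key-value mappings (YAML on disk).
``validate_config`` fills documented defaults, logs every default it fills,
and reports *all* invariant violations at once rather than only the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .errors import ConfigError

log = logging.getLogger(__name__)

#: Clapp-Hornberger-style texture defaults: saturated conductivity K_s (mm/h),
#: pore-size exponent b (leakage exponent c = 2b + 3), porosity, field capacity
#: and wilting point as volumetric water contents.
TEXTURE_CLASSES = {
    "sand": dict(k_s=210.0, b=4.05, porosity=0.395, field_capacity=0.125, wilting_point=0.035),
    "loamy_sand": dict(k_s=61.0, b=4.38, porosity=0.410, field_capacity=0.150, wilting_point=0.047),
    "sandy_loam": dict(k_s=26.0, b=4.90, porosity=0.435, field_capacity=0.195, wilting_point=0.068),
    "loam": dict(k_s=25.0, b=5.39, porosity=0.451, field_capacity=0.270, wilting_point=0.117),
    "silt_loam": dict(k_s=13.0, b=5.30, porosity=0.485, field_capacity=0.320, wilting_point=0.133),
    "clay_loam": dict(k_s=8.8, b=8.52, porosity=0.476, field_capacity=0.340, wilting_point=0.197),
    "clay": dict(k_s=4.6, b=11.40, porosity=0.482, field_capacity=0.400, wilting_point=0.272),
}


@dataclass
class FeedstockEvent:
    """One rock application: when, how much, of what."""

    date: pd.Timestamp
    rate: float  # kg rock m-2
    mineral_fractions: dict[str, float] = field(default_factory=dict)
    specific_surface_area: float = 3000.0  # m2 kg-1 (BET, milled basalt)


@dataclass
class SiteConfig:
    latitude: float = 40.0
    z_a: float = 0.30               # active-layer depth, m
    texture_class: str = "loam"
    porosity: float | None = None   # filled from texture if unset
    field_capacity: float | None = None
    wilting_point: float | None = None
    k_s: float | None = None        # mm h-1
    b_exponent: float | None = None
    cec: float = 50.0               # mol_c m-2


@dataclass
class ScheduleConfig:
    start: pd.Timestamp = pd.Timestamp("2017-01-01")
    end: pd.Timestamp = pd.Timestamp("2017-12-31")
    spinup_years: int = 0


@dataclass
class ChemistryConfig:
    dic_rain: float = 0.2           # g C m-3 rainwater DIC
    k_p: float = 0.5                # carbonate precip/dissolution rate, g C m-2 d-1
    k_mg: float = 1.0               # Gaines-Thomas selectivity vs Ca (eq basis)
    k_k: float = 0.2
    k_na: float = 0.05
    k_h: float = 1.0e8              # exchangeable-acidity selectivity (calibration)
    soil_co2_init_ppm: float = 4000.0
    freeze_ph: float | None = None  # diagnostic: hold weathering pH fixed
    include_monovalent_cdr: bool = False


@dataclass
class HydrologyConfig:
    damping_days: float = 10.0      # soil-temperature e-folding time
    pt_alpha: float = 1.26          # Priestley-Taylor coefficient
    albedo: float = 0.23
    snow_ddf: float = 0.15          # degree-day melt factor, mm degC-1 h-1
    lw_loss: float = 60.0           # W m-2 net longwave loss in the PET proxy
    s_wilt_stress: float = 0.15     # s_eff at which plant water stress hits 0
    s_star_stress: float = 0.50     # s_eff above which plants are unstressed
    soil_temp_floor: bool = False


@dataclass
class VegetationConfig:
    pft: str = "maize"
    rotation: dict[int, str] = field(default_factory=dict)  # year index -> pft
    trait_overrides: dict = field(default_factory=dict)
    seed_carbon: float = 20.0       # g C m-2 added at planting (ledger input)


@dataclass
class ExternalInputs:
    n_deposition: float = 2.0e-3    # g N m-2 d-1
    p_deposition: float = 5.0e-5
    ca_deposition: float = 4.0e-4
    mg_deposition: float = 1.5e-4
    k_deposition: float = 2.0e-4
    na_deposition: float = 6.0e-4
    anion_deposition: float = 2.0e-5  # mol_c m-2 d-1
    fertilisation: list[dict] = field(default_factory=list)  # {date, n, p}


@dataclass
class InitialState:
    soc: dict[str, float] = field(default_factory=lambda: dict(
        poc_lignin=600.0, poc_cellulose=900.0, maoc=4000.0, doc=15.0,
        bacteria=60.0, fungi=60.0, am=10.0, em=5.0,
        enz_bact=1.0, enz_fungi=1.0, earthworms=8.0,
    ))
    litter: dict[str, float] = field(default_factory=lambda: dict(
        ag_leaf=120.0, ag_wood=40.0, ag_fine=30.0, ag_repro=10.0,
        bg_root=90.0, bg_wood=20.0, bg_fine=40.0, bg_coarse=20.0,
    ))
    solutes: dict[str, float] = field(default_factory=lambda: dict(
        Ca=8.0, Mg=3.0, K=4.0, Na=2.0, NH4=0.5, NO3=1.5, TPO4=0.3,
        Si=5.0, Al=0.05, An_r=0.25,
    ))
    exchange_fractions: dict[str, float] = field(default_factory=lambda: dict(
        Ca=0.65, Mg=0.15, K=0.04, Na=0.01, acidity=0.15,
    ))
    nutrients: dict[str, float] = field(default_factory=lambda: dict(
        org_N=600.0, org_P=80.0,
        K_primary=5000.0, Ca_primary=3000.0, Mg_primary=2000.0,
        Si_primary=20000.0, P_primary=100.0,
        K_secondary=0.0, Ca_secondary=0.0, Mg_secondary=0.0,
        Si_secondary=0.0, P_secondary=0.0,
    ))
    s_eff: float = 0.55


@dataclass
class SimulationConfig:
    site: SiteConfig = field(default_factory=SiteConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    feedstock_events: list[FeedstockEvent] = field(default_factory=list)
    f_d: float = 1.0
    chemistry: ChemistryConfig = field(default_factory=ChemistryConfig)
    hydrology: HydrologyConfig = field(default_factory=HydrologyConfig)
    vegetation: VegetationConfig = field(default_factory=VegetationConfig)
    external: ExternalInputs = field(default_factory=ExternalInputs)
    initial: InitialState = field(default_factory=InitialState)
    biogeochem_overrides: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"]["start"] = str(self.schedule.start.date())
        d["schedule"]["end"] = str(self.schedule.end.date())
        for ev in d["feedstock_events"]:
            ev["date"] = str(pd.Timestamp(ev["date"]).date())
        return d


def _build_section(cls, raw: dict, violations: list[str], path: str):
    known = {f for f in cls.__dataclass_fields__}
    obj = cls()
    for key, val in raw.items():
        if key not in known:
            violations.append(f"{path}.{key}: unknown key")
            continue
        setattr(obj, key, val)
    for key in known - set(raw):
        log.debug("config default filled: %s.%s = %r", path, key, getattr(obj, key))
    return obj


def validate_config(raw: dict) -> SimulationConfig:
    """Build a fully populated config from a hierarchical mapping.

    Fills documented defaults (each filled default is logged at DEBUG) and
    raises :class:`ConfigError` listing *all* violations found.
    """
    if raw is None:
        raw = {}
    violations: list[str] = []
    cfg = SimulationConfig()

    cfg.site = _build_section(SiteConfig, raw.get("site", {}), violations, "site")
    sched_raw = dict(raw.get("schedule", {}))
    for key in ("start", "end"):
        if key in sched_raw:
            try:
                sched_raw[key] = pd.Timestamp(sched_raw[key])
            except (ValueError, TypeError):
                violations.append(f"schedule.{key}: unparseable date {sched_raw[key]!r}")
                sched_raw.pop(key)
    cfg.schedule = _build_section(ScheduleConfig, sched_raw, violations, "schedule")
    cfg.chemistry = _build_section(ChemistryConfig, raw.get("chemistry", {}), violations, "chemistry")
    cfg.hydrology = _build_section(HydrologyConfig, raw.get("hydrology", {}), violations, "hydrology")
    veg_raw = dict(raw.get("vegetation", {}))
    if "rotation" in veg_raw:
        veg_raw["rotation"] = {int(k): v for k, v in dict(veg_raw["rotation"]).items()}
    cfg.vegetation = _build_section(VegetationConfig, veg_raw, violations, "vegetation")
    cfg.external = _build_section(ExternalInputs, raw.get("external", {}), violations, "external")
    init_raw = dict(raw.get("initial", {}))
    cfg.initial = InitialState()
    for key, val in init_raw.items():
        if key == "s_eff":
            cfg.initial.s_eff = float(val)
        elif hasattr(cfg.initial, key):
            getattr(cfg.initial, key).update(val)
        else:
            violations.append(f"initial.{key}: unknown key")
    cfg.biogeochem_overrides = dict(raw.get("biogeochem", {}))

    fs_raw = raw.get("feedstock", {})
    cfg.f_d = float(fs_raw.get("f_d", 1.0))
    if cfg.f_d < 0:
        violations.append(f"feedstock.f_d: must be >= 0, got {cfg.f_d}")
    for i, ev in enumerate(fs_raw.get("events", [])):
        try:
            date = pd.Timestamp(ev["date"])
        except (KeyError, ValueError, TypeError):
            violations.append(f"feedstock.events[{i}].date: missing or unparseable")
            continue
        rate = float(ev.get("rate", 0.0))
        fracs = {k: float(v) for k, v in dict(ev.get("mineral_fractions", {})).items()}
        ssa = float(ev.get("specific_surface_area", 3000.0))
        if rate < 0:
            violations.append(f"feedstock.events[{i}].rate: must be >= 0, got {rate}")
        if any(f < 0 or f > 1 for f in fracs.values()):
            violations.append(f"feedstock.events[{i}]: mineral fraction outside [0, 1]")
        if fracs and sum(fracs.values()) > 1.0 + 1e-9:
            violations.append(
                f"feedstock.events[{i}]: mineral fractions sum to "
                f"{sum(fracs.values()):.6g} > 1"
            )
        elif fracs and sum(fracs.values()) < 1.0 - 1e-9:
            log.debug(
                "feedstock event %d: mineral fractions sum to %.4g; the "
                "remainder is treated as unreactive mass", i, sum(fracs.values())
            )
        if ssa <= 0:
            violations.append(f"feedstock.events[{i}].specific_surface_area: must be > 0")
        cfg.feedstock_events.append(FeedstockEvent(date, rate, fracs, ssa))

    # texture defaults
    site = cfg.site
    tex = TEXTURE_CLASSES.get(site.texture_class)
    if tex is None:
        violations.append(
            f"site.texture_class: unknown class {site.texture_class!r} "
            f"(known: {sorted(TEXTURE_CLASSES)})"
        )
    else:
        for key in ("porosity", "field_capacity", "wilting_point", "k_s"):
            if getattr(site, key) is None:
                setattr(site, key, tex[key])
                log.debug("config default filled: site.%s = %r (texture)", key, tex[key])
        if site.b_exponent is None:
            site.b_exponent = tex["b"]

    if site.z_a <= 0:
        violations.append(f"site.z_a: must be > 0, got {site.z_a}")
    if site.porosity is not None and not (0 < site.porosity < 1):
        violations.append(f"site.porosity: must be in (0, 1), got {site.porosity}")
    if (
        site.wilting_point is not None
        and site.field_capacity is not None
        and site.porosity is not None
        and not (site.wilting_point < site.field_capacity < site.porosity)
    ):
        violations.append(
            "site: require wilting_point < field_capacity < porosity, got "
            f"{site.wilting_point} / {site.field_capacity} / {site.porosity}"
        )
    if site.cec <= 0:
        violations.append(f"site.cec: must be > 0, got {site.cec}")
    if cfg.schedule.end < cfg.schedule.start:
        violations.append("schedule: end date precedes start date")
    if cfg.schedule.spinup_years < 0:
        violations.append("schedule.spinup_years: must be >= 0")
    exch = cfg.initial.exchange_fractions
    if abs(sum(exch.values()) - 1.0) > 1e-9:
        violations.append(
            f"initial.exchange_fractions: sum to {sum(exch.values()):.6g}, expected 1"
        )
    for ev in cfg.feedstock_events:
        if not (cfg.schedule.start <= ev.date <= cfg.schedule.end):
            violations.append(
                f"feedstock event on {ev.date.date()} outside simulation window"
            )
    for fert in cfg.external.fertilisation:
        try:
            fdate = pd.Timestamp(fert["date"])
        except (KeyError, ValueError, TypeError):
            violations.append("external.fertilisation: event missing a parseable date")
            continue
        if not (cfg.schedule.start <= fdate <= cfg.schedule.end):
            violations.append(
                f"fertilisation event on {fdate.date()} outside simulation window"
            )
    if cfg.chemistry.freeze_ph is not None and not (2.0 <= cfg.chemistry.freeze_ph <= 12.0):
        violations.append("chemistry.freeze_ph: must lie in [2, 12]")

    if violations:
        raise ConfigError(
            "configuration invalid:\n  - " + "\n  - ".join(violations)
        )
    return cfg


def load_config(path) -> SimulationConfig:
    """Read a YAML config file and validate it."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
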