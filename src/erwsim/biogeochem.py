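"""Daily microbially explicit SOC decomposition and element budgets.

The soil organic carbon scheme follows the MEND lineage: particulate
(lignin-like and cellulose-like), mineral-associated and dissolved organic
carbon pools, explicit bacterial/fungal biomass, extracellular enzymes,
arbuscular/ecto-mycorrhizae fed from the plant, and an earthworm pool that
grazes POC only.  Depolymerisation fluxes are Michaelis-Menten in
substrate, first-order in the producing enzyme, and multiplied by
temperature, moisture and pH modifiers.  Litter (8 above/below-ground
pools carrying their own element stoichiometry) decays with linear
kinetics.

Element budgets (N, P, K, Ca, Mg, Si, Na, Al, residual anions) each close
a full ledger every day: litter release is split between direct
mineralisation, organic leaching and the stable SOM organic pool; the SOM
organic pool releases elements in proportion to the carbon
depolymerisation rate; microbial immobilisation/mineralisation closes N
and P stoichiometry against the microbial C:N and C:P targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources

import pandas as pd

from .errors import ConservationError, ParameterError

LITTER_POOLS = (
    "ag_leaf", "ag_wood", "ag_fine", "ag_repro",
    "bg_root", "bg_wood", "bg_fine", "bg_coarse",
)
ORG_ELEMENTS = ("N", "P", "K", "Ca", "Mg", "Si", "Na")


def load_biogeochem_params(overrides: dict[str, float] | None = None) -> dict[str, float]:
    """Parameter set from the packaged table, with optional overrides.

    The table is delimited text with one row per named parameter carrying
    value, units and a source tag.
    """
    src = resources.files("erwsim.data").joinpath("biogeochem_params.tsv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t")
    params = dict(zip(df["parameter"], df["value"].astype(float)))
    if overrides:
        unknown = set(overrides) - set(params)
        if unknown:
            raise ParameterError(f"unknown biogeochem parameter(s): {sorted(unknown)}")
        params.update(overrides)
    return params


@dataclass
class EnvModifiers:
    """Dimensionless [0, 1] multipliers on biological rates."""

    f_t: float = 1.0
    f_w: float = 1.0
    f_ph: float = 1.0

    @property
    def microbial(self) -> float:
        return self.f_t * self.f_w * self.f_ph

    @property
    def litter(self) -> float:
        return self.f_t * self.f_w


def env_modifiers(
    soil_temp: float, s_eff: float, ph: float, params: dict[str, float]
) -> EnvModifiers:
    """Q10-style temperature, quadratic-optimum moisture, Gaussian pH."""
    f_t = min(1.0, params["q10"] ** ((soil_temp - params["t_ref"]) / 10.0))
    dev = (s_eff - params["s_opt"]) / params["s_opt"]
    f_w = max(0.0, 1.0 - dev * dev)
    f_ph = math.exp(-0.5 * ((ph - params["ph_opt"]) / params["ph_sigma"]) ** 2)
    return EnvModifiers(f_t=max(0.0, f_t), f_w=f_w, f_ph=f_ph)


def _zero_elements() -> dict[str, float]:
    return {el: 0.0 for el in ("C",) + ORG_ELEMENTS}


@dataclass
class SOCPools:
    """Soil organic carbon state, g C m-2 (litter pools carry elements)."""

    poc_lignin: float = 600.0
    poc_cellulose: float = 900.0
    maoc: float = 4000.0
    doc: float = 15.0
    bacteria: float = 60.0
    fungi: float = 60.0
    am: float = 10.0
    em: float = 5.0
    enz_bact: float = 1.0
    enz_fungi: float = 1.0
    earthworms: float = 8.0
    litter: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: _zero_elements() for p in LITTER_POOLS}
    )

    def litter_carbon(self) -> float:
        return sum(pool["C"] for pool in self.litter.values())

    def litter_element(self, el: str) -> float:
        return sum(pool[el] for pool in self.litter.values())

    def total_carbon(self) -> float:
        scalar = (
            self.poc_lignin + self.poc_cellulose + self.maoc + self.doc
            + self.bacteria + self.fungi + self.am + self.em
            + self.enz_bact + self.enz_fungi + self.earthworms
        )
        return scalar + self.litter_carbon()

    def scalar_pools(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "litter"
        }


@dataclass
class NutrientPools:
    """Organic, primary-mineral and secondary-mineral element pools, g m-2."""

    org: dict[str, float] = field(
        default_factory=lambda: {el: 0.0 for el in ORG_ELEMENTS}
    )
    primary: dict[str, float] = field(
        default_factory=lambda: dict(K=5000.0, Ca=3000.0, Mg=2000.0, Si=20000.0, P=100.0)
    )
    secondary: dict[str, float] = field(
        default_factory=lambda: dict(K=0.0, Ca=0.0, Mg=0.0, Si=0.0, P=0.0)
    )


def leach_flux(pool_mass: float, leach_rate_step: float) -> float:
    """Proportional leaching, capped at the pool mass per step."""
    if pool_mass < 0 or leach_rate_step < 0:
        raise ParameterError("pool mass and leach rate must be >= 0")
    return min(pool_mass * leach_rate_step, pool_mass)


def step_soc(
    pools: SOCPools,
    env: EnvModifiers,
    litter_in: dict[str, dict[str, float]] | None,
    params: dict[str, float],
    myco_c_supply: float = 0.0,
    dt: float = 1.0,
    _halvings: int = 0,
) -> tuple[SOCPools, dict[str, float]]:
    """One daily SOC step; returns the updated pools and a flux record.

    Fluxes include the depolymerisation terms (``F2l``, ``F2cb``, ``F2cf``,
    ``F3b``, ``F3f``), heterotrophic respiration components
    (``r_microbe``, ``r_litter``, ``r_ew``), the litter element release
    ``litter_release_<el>``, total SOM depolymerised C ``decomp_c`` and the
    emergent microbial carbon-use efficiency ``cue``.  If a pool would go
    negative the step is retried at half the time step (up to 4 halvings)
    before raising :class:`ConservationError`.
    """
    import copy

    snapshot = copy.deepcopy(pools)
    try:
        return _step_soc_once(pools, env, litter_in, params, myco_c_supply, dt)
    except ConservationError:
        if _halvings >= 4:
            raise
        # restore and integrate as two half steps (litter lands in the second)
        pools.__dict__.update(copy.deepcopy(snapshot).__dict__)
        pools, fx1 = step_soc(
            pools, env, None, params, myco_c_supply / 2.0, dt / 2.0, _halvings + 1
        )
        pools, fx2 = step_soc(
            pools, env, litter_in, params, myco_c_supply / 2.0, dt / 2.0, _halvings + 1
        )
        merged = {k: fx1.get(k, 0.0) + fx2.get(k, 0.0) for k in set(fx1) | set(fx2)}
        up = merged.get("doc_uptake", 0.0)
        merged["cue"] = merged.get("growth", 0.0) / up if up > 0.0 else 0.0
        return pools, merged


def _step_soc_once(
    pools: SOCPools,
    env: EnvModifiers,
    litter_in: dict[str, dict[str, float]] | None,
    params: dict[str, float],
    myco_c_supply: float,
    dt: float,
) -> tuple[SOCPools, dict[str, float]]:
    p = params
    fm = env.microbial
    fl = env.litter
    fx = {k: 0.0 for k in (
        "F2l", "F2cb", "F2cf", "F3b", "F3f", "doc_uptake", "growth",
        "r_microbe", "r_litter", "r_ew", "r_het", "decomp_c", "cue",
    )}
    for el in ORG_ELEMENTS:
        fx[f"litter_release_{el}"] = 0.0

    # --- litter: linear kinetics, elements released congruently
    for name, pool in pools.litter.items():
        k = p[f"litter_k_{name}"] * fl * dt
        k = min(k, 1.0)
        c_dec = pool["C"] * k
        pool["C"] -= c_dec
        resp = c_dec * p["litter_resp_frac"]
        fx["r_litter"] += resp
        rest = c_dec - resp
        pools.poc_lignin += rest * p["litter_to_lignin"]
        pools.poc_cellulose += rest * p["litter_to_cellulose"]
        pools.doc += rest * p["litter_to_doc"]
        for el in ORG_ELEMENTS:
            rel = pool[el] * k
            pool[el] -= rel
            fx[f"litter_release_{el}"] += rel

    # --- enzymatic depolymerisation (Michaelis-Menten in substrate)
    def mm(vmax: float, enz: float, substrate: float, km: float) -> float:
        if substrate <= 0.0 or enz <= 0.0:
            return 0.0
        return vmax * enz * substrate / (km + substrate) * fm * dt

    f2l = mm(p["v_lignin"], pools.enz_fungi, pools.poc_lignin, p["k_lignin"])
    f2l = min(f2l, pools.poc_lignin)
    f2cb = mm(p["v_cellulose"], pools.enz_bact, pools.poc_cellulose, p["k_cellulose"])
    f2cf = mm(p["v_cellulose"], pools.enz_fungi, pools.poc_cellulose, p["k_cellulose"])
    tot_cell = f2cb + f2cf
    if tot_cell > pools.poc_cellulose > 0.0:
        scale = pools.poc_cellulose / tot_cell
        f2cb *= scale
        f2cf *= scale
    f3b = mm(p["v_maoc"], pools.enz_bact, pools.maoc, p["k_maoc"])
    f3f = mm(p["v_maoc"], pools.enz_fungi, pools.maoc, p["k_maoc"])
    tot_maoc = f3b + f3f
    if tot_maoc > pools.maoc > 0.0:
        scale = pools.maoc / tot_maoc
        f3b *= scale
        f3f *= scale

    pools.poc_lignin -= f2l
    pools.poc_cellulose -= f2cb + f2cf
    pools.maoc -= f3b + f3f
    poc_dec = f2l + f2cb + f2cf
    # POC -> MAOC routing saturates with mineral-surface occupancy
    route = p["f_maoc_max"] * p["k_maoc_half"] / (p["k_maoc_half"] + pools.maoc)
    pools.maoc += poc_dec * route
    pools.doc += poc_dec * (1.0 - route) + f3b + f3f
    fx.update(F2l=f2l, F2cb=f2cb, F2cf=f2cf, F3b=f3b, F3f=f3f)
    fx["decomp_c"] = poc_dec + f3b + f3f

    # --- microbial DOC uptake, growth, maintenance, enzymes, mortality
    biomass = pools.bacteria + pools.fungi
    uptake = 0.0
    if biomass > 0.0 and pools.doc > 0.0:
        uptake = min(
            p["v_doc"] * biomass * pools.doc / (p["k_doc"] + pools.doc) * fm * dt,
            pools.doc,
        )
    pools.doc -= uptake
    growth = p["yield_microbe"] * uptake
    resp_growth = uptake - growth
    share_b = pools.bacteria / biomass if biomass > 0.0 else 0.5
    pools.bacteria += growth * share_b
    pools.fungi += growth * (1.0 - share_b)

    maint_b = min(p["maint_rate"] * env.f_t * dt, 1.0) * pools.bacteria
    maint_f = min(p["maint_rate"] * env.f_t * dt, 1.0) * pools.fungi
    pools.bacteria -= maint_b
    pools.fungi -= maint_f

    prod_b = min(p["enz_production"] * dt, 1.0) * pools.bacteria
    prod_f = min(p["enz_production"] * dt, 1.0) * pools.fungi
    pools.bacteria -= prod_b
    pools.fungi -= prod_f
    pools.enz_bact += prod_b
    pools.enz_fungi += prod_f
    turn_b = min(p["enz_turnover"] * dt, 1.0) * pools.enz_bact
    turn_f = min(p["enz_turnover"] * dt, 1.0) * pools.enz_fungi
    pools.enz_bact -= turn_b
    pools.enz_fungi -= turn_f
    pools.doc += turn_b + turn_f

    dead = min(p["mortality"] * dt, 1.0) * (pools.bacteria + pools.fungi)
    pools.bacteria *= 1.0 - min(p["mortality"] * dt, 1.0)
    pools.fungi *= 1.0 - min(p["mortality"] * dt, 1.0)
    pools.poc_cellulose += dead * p["dead_to_poc"]
    pools.doc += dead * p["dead_to_doc"]
    pools.maoc += dead * p["dead_to_maoc"]
    fx["mortality"] = dead

    # --- mycorrhizae: plant-fed, no enzymes of their own here
    myco_resp = myco_c_supply * p["myco_resp_frac"]
    myco_gain = myco_c_supply - myco_resp
    tot_myc = pools.am + pools.em
    share_am = pools.am / tot_myc if tot_myc > 0.0 else 0.5
    pools.am += myco_gain * share_am
    pools.em += myco_gain * (1.0 - share_am)
    m_myc = min(p["myco_maint"] * env.f_t * dt, 1.0)
    myco_maint = m_myc * (pools.am + pools.em)
    pools.am -= m_myc * pools.am
    pools.em -= m_myc * pools.em
    d_myc = min(p["myco_mortality"] * dt, 1.0)
    pools.doc += d_myc * (pools.am + pools.em)
    pools.am *= 1.0 - d_myc
    pools.em *= 1.0 - d_myc

    fx["r_microbe"] = resp_growth + maint_b + maint_f + myco_resp + myco_maint
    fx["doc_uptake"] = uptake
    fx["growth"] = growth
    fx["cue"] = growth / uptake if uptake > 0.0 else 0.0

    # --- earthworms graze POC only
    poc_tot = pools.poc_lignin + pools.poc_cellulose
    if pools.earthworms > 0.0 and poc_tot > 0.0:
        intake = min(
            p["ew_graze"] * pools.earthworms * poc_tot / (p["k_ew"] + poc_tot)
            * env.f_t * env.f_w * dt,
            poc_tot,
        )
        assim = intake * p["ew_assim"]
        # unassimilated C returns to POC, so only the assimilated part leaves
        frac_l = pools.poc_lignin / poc_tot
        pools.poc_lignin -= assim * frac_l
        pools.poc_cellulose -= assim * (1.0 - frac_l)
        r_ew = assim * p["ew_resp_frac"]
        pools.earthworms += assim - r_ew
        fx["r_ew"] = r_ew
    dead_ew = min(p["ew_mortality"] * dt, 1.0) * pools.earthworms
    pools.earthworms -= dead_ew
    pools.poc_cellulose += dead_ew

    # --- litter input arrives at the end of the day
    if litter_in:
        for name, content in litter_in.items():
            pool = pools.litter[name]
            for el, mass in content.items():
                pool[el] = pool.get(el, 0.0) + mass

    fx["r_het"] = fx["r_microbe"] + fx["r_litter"] + fx["r_ew"]

    for name, val in pools.scalar_pools().items():
        if val < 0.0:
            raise ConservationError(f"negative SOC pool {name}={val}")
    return pools, fx


def som_element_release(
    nutrients: NutrientPools,
    pools: SOCPools,
    decomp_c: float,
) -> dict[str, float]:
    """Elements released from the stable SOM organic pool this day.

    Release is proportional to the fraction of POC + MAOC depolymerised,
    so element turnover tracks carbon turnover.
    """
    som_c = pools.poc_lignin + pools.poc_cellulose + pools.maoc
    if som_c <= 0.0 or decomp_c <= 0.0:
        return {el: 0.0 for el in ORG_ELEMENTS}
    frac = min(decomp_c / (som_c + decomp_c), 1.0)
    out = {}
    for el in ORG_ELEMENTS:
        rel = nutrients.org[el] * frac
        nutrients.org[el] -= rel
        out[el] = rel
    return out


def partition_litter_release(
    litter_release: float, lam: float, f_org_lea: float
) -> tuple[float, float, float]:
    """Split litter-released element into (mineral, organic-leached, to-SOM)."""
    mineral = lam * (1.0 - f_org_lea) * litter_release
    org_leach = lam * f_org_lea * litter_release
    to_som = litter_release - mineral - org_leach
    return mineral, org_leach, to_som


def step_nitrogen(
    solutes: dict[str, float],
    nutrients: NutrientPools,
    env: EnvModifiers,
    params: dict[str, float],
    litter_release_n: float,
    som_release_n: float,
    immob_demand_n: float,
    leach_rate: float,
    ext_n: float,
    s_eff: float,
    ph: float,
    dt: float = 1.0,
) -> dict[str, float]:
    """Daily NH4+/NO3- balances.

    Terms: litter-decomposition input split by the leaching coefficient
    ``lambda_n`` and organic-leaching fraction, SOM mineralisation,
    microbial immobilisation (NH4 first, then NO3, capped by availability)
    or net mineralisation, nitrification, NH3 volatilisation (rising with
    pH through the NH3/NH4+ speciation fraction), denitrification on a
    high-saturation ramp, proportional leaching and external inputs.
    Plant uptake is applied by the vegetation module.
    """
    p = params
    fx = {}
    mineral_in, org_leach, to_som = partition_litter_release(
        litter_release_n, p["lambda_n"], p["f_org_lea"]
    )
    nutrients.org["N"] += to_som
    solutes["NH4"] += mineral_in + som_release_n + ext_n
    fx["n_mineral_input"] = mineral_in + som_release_n
    fx["n_org_leach"] = org_leach
    fx["n_external"] = ext_n

    # immobilisation: demand from microbial growth stoichiometry
    immob = 0.0
    if immob_demand_n > 0.0:
        take_nh4 = min(immob_demand_n, solutes["NH4"])
        solutes["NH4"] -= take_nh4
        rem = immob_demand_n - take_nh4
        take_no3 = min(rem, solutes["NO3"])
        solutes["NO3"] -= take_no3
        immob = take_nh4 + take_no3
        nutrients.org["N"] += immob
    elif immob_demand_n < 0.0:  # net mineralisation from microbial turnover
        rel = min(-immob_demand_n, nutrients.org["N"])
        nutrients.org["N"] -= rel
        solutes["NH4"] += rel
        immob = -rel
    fx["n_immobilised"] = immob

    nitr = min(p["k_nitrification"] * env.f_t * env.f_w * dt, 1.0) * solutes["NH4"]
    solutes["NH4"] -= nitr
    solutes["NO3"] += nitr
    fx["nitrification"] = nitr

    nh3_frac = 1.0 / (1.0 + 10.0 ** (9.25 - ph))
    nvol = min(p["k_volatilisation"] * nh3_frac * dt, 1.0) * solutes["NH4"]
    solutes["NH4"] -= nvol
    fx["n_volatilised"] = nvol

    f_anx = max(0.0, (s_eff - 0.8) / 0.2) ** 2
    denit = min(p["k_denitrification"] * f_anx * dt, 1.0) * solutes["NO3"]
    solutes["NO3"] -= denit
    fx["n_denitrified"] = denit

    lk_nh4 = leach_flux(solutes["NH4"], leach_rate)
    lk_no3 = leach_flux(solutes["NO3"], leach_rate)
    solutes["NH4"] -= lk_nh4
    solutes["NO3"] -= lk_no3
    fx["n_leached"] = lk_nh4 + lk_no3
    return fx


def step_phosphorus(
    solutes: dict[str, float],
    nutrients: NutrientPools,
    env: EnvModifiers,
    params: dict[str, float],
    litter_release_p: float,
    som_release_p: float,
    immob_demand_p: float,
    leach_rate: float,
    ext_p: float,
    ew_p: float = 0.0,
    dt: float = 1.0,
) -> dict[str, float]:
    """Daily TPO4 balance: SOM input, immobilisation/mineralisation,
    secondary fixation (first-order), primary-mineral input, leaching,
    external inputs and feedstock-derived P."""
    if ew_p < 0.0:
        raise ParameterError("feedstock P release must be >= 0")
    p = params
    fx = {}
    mineral_in, org_leach, to_som = partition_litter_release(
        litter_release_p, p["lambda_p"], p["f_org_lea"]
    )
    nutrients.org["P"] += to_som
    pri = min(p["k_pri_p"] * dt, 1.0) * nutrients.primary["P"]
    nutrients.primary["P"] -= pri
    solutes["TPO4"] += mineral_in + som_release_p + ext_p + pri + ew_p
    fx["p_mineral_input"] = mineral_in + som_release_p
    fx["p_org_leach"] = org_leach
    fx["p_primary"] = pri
    fx["p_external"] = ext_p
    fx["p_feedstock"] = ew_p

    immob = 0.0
    if immob_demand_p > 0.0:
        immob = min(immob_demand_p, solutes["TPO4"])
        solutes["TPO4"] -= immob
        nutrients.org["P"] += immob
    elif immob_demand_p < 0.0:
        rel = min(-immob_demand_p, nutrients.org["P"])
        nutrients.org["P"] -= rel
        solutes["TPO4"] += rel
        immob = -rel
    fx["p_immobilised"] = immob

    sec = min(p["k_fix_p"] * dt, 1.0) * solutes["TPO4"]
    solutes["TPO4"] -= sec
    nutrients.secondary["P"] += sec
    fx["p_fixed"] = sec

    lk = leach_flux(solutes["TPO4"], leach_rate)
    solutes["TPO4"] -= lk
    fx["p_leached"] = lk
    return fx


def step_cations(
    solutes: dict[str, float],
    nutrients: NutrientPools,
    params: dict[str, float],
    litter_release: dict[str, float],
    som_release: dict[str, float],
    leach_rate: float,
    ext: dict[str, float],
    dt: float = 1.0,
) -> dict[str, float]:
    """Daily K/Ca/Mg solution balances (exchange runs in the chemistry
    sub-steps; feedstock release enters there as well)."""
    p = params
    fx = {}
    for x in ("K", "Ca", "Mg"):
        mineral_in, org_leach, to_som = partition_litter_release(
            litter_release.get(x, 0.0), p["lambda_x"], p["f_org_lea"]
        )
        nutrients.org[x] += to_som
        pri = min(p["k_pri_cation"] * dt, 1.0) * nutrients.primary[x]
        nutrients.primary[x] -= pri
        solutes[x] += mineral_in + som_release.get(x, 0.0) + pri + ext.get(x, 0.0)
        sec = min(p["k_fix_cation"] * dt, 1.0) * solutes[x]
        solutes[x] -= sec
        nutrients.secondary[x] += sec
        lk = leach_flux(solutes[x], leach_rate)
        solutes[x] -= lk
        fx[f"{x}_mineral_input"] = mineral_in + som_release.get(x, 0.0)
        fx[f"{x}_org_leach"] = org_leach
        fx[f"{x}_primary"] = pri
        fx[f"{x}_fixed"] = sec
        fx[f"{x}_leached"] = lk
        fx[f"{x}_external"] = ext.get(x, 0.0)
    return fx


def step_si_na_al_anions(
    solutes: dict[str, float],
    nutrients: NutrientPools,
    params: dict[str, float],
    litter_release: dict[str, float],
    som_release: dict[str, float],
    leach_rate: float,
    ext: dict[str, float],
    dt: float = 1.0,
) -> dict[str, float]:
    """Si (cation template without exchange), Na (passive uptake only),
    Al (no uptake), and the residual strong-anion pool."""
    p = params
    fx = {}
    # silicon
    m_in, org_leach, to_som = partition_litter_release(
        litter_release.get("Si", 0.0), p["lambda_x"], p["f_org_lea"]
    )
    nutrients.org["Si"] += to_som
    pri = min(p["k_pri_si"] * dt, 1.0) * nutrients.primary["Si"]
    nutrients.primary["Si"] -= pri
    solutes["Si"] += m_in + som_release.get("Si", 0.0) + pri + ext.get("Si", 0.0)
    sec = min(p["k_fix_si"] * dt, 1.0) * solutes["Si"]
    solutes["Si"] -= sec
    nutrients.secondary["Si"] += sec
    lk_si = leach_flux(solutes["Si"], leach_rate)
    solutes["Si"] -= lk_si
    fx.update(
        Si_mineral_input=m_in + som_release.get("Si", 0.0), Si_org_leach=org_leach,
        Si_primary=pri, Si_fixed=sec, Si_leached=lk_si,
        Si_external=ext.get("Si", 0.0),
    )
    # sodium
    m_in, org_leach, to_som = partition_litter_release(
        litter_release.get("Na", 0.0), p["lambda_x"], p["f_org_lea"]
    )
    nutrients.org["Na"] += to_som
    solutes["Na"] += m_in + som_release.get("Na", 0.0) + ext.get("Na", 0.0)
    lk_na = leach_flux(solutes["Na"], leach_rate)
    solutes["Na"] -= lk_na
    fx.update(
        Na_mineral_input=m_in + som_release.get("Na", 0.0), Na_org_leach=org_leach,
        Na_leached=lk_na, Na_external=ext.get("Na", 0.0),
    )
    # aluminium: conservative mobile pool, no uptake
    solutes["Al"] += ext.get("Al", 0.0)
    lk_al = leach_flux(solutes["Al"], leach_rate)
    solutes["Al"] -= lk_al
    fx.update(Al_leached=lk_al, Al_external=ext.get("Al", 0.0))
    # residual anions (mol_c m-2)
    solutes["An_r"] += ext.get("An_r", 0.0)
    lk_an = leach_flux(solutes["An_r"], leach_rate)
    solutes["An_r"] -= lk_an
    fx.update(An_r_leached=lk_an, An_r_external=ext.get("An_r", 0.0))
    return fx
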