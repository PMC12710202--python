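"""Single-canopy plant carbon, respiration, nutrient uptake and litterfall.

Photosynthesis is a light-use-efficiency surrogate: GPP = LUE * APAR * f_T
* water_stress * nutrient_stress with APAR = 0.45 * SW * (1 - e^(-0.5 LAI)).
Carbon moves through seven pools (leaves, dead standing leaves, sapwood,
heartwood, fine roots, non-structural carbohydrate NSC, reproductive);
maintenance respiration is paid from NSC (growth is suppressed and a
starvation flag raised when NSC empties), growth respiration is a fixed
fraction of new growth.  Each element (N, P, K, Ca, Mg, Si, Na) has a
structural content tied to tissue stoichiometry plus a reserve pool;
uptake combines transpiration-driven passive absorption with
Michaelis-Menten active transport scaled by fine-root mass and demand, and
is suppressed linearly once a reserve passes 80% of its maximum capacity.
Na and residual anions are passive-only; Al is never taken up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .constants import ATOMIC_MASS
from .errors import ConfigError, ParameterError

PLANT_ELEMENTS = ("N", "P", "K", "Ca", "Mg", "Si", "Na")
LIVE_TISSUES = ("leaves", "sapwood", "fine_roots", "repro")


@dataclass
class PlantTraits:
    name: str = "maize"
    lue: float = 3.0                  # g C per MJ APAR
    sla: float = 0.025                # m2 leaf per g leaf C
    alloc: dict[str, float] = field(
        default_factory=lambda: dict(leaves=0.35, sapwood=0.30, fine_roots=0.20, repro=0.15)
    )
    turnover: dict[str, float] = field(  # d-1
        default_factory=lambda: dict(
            leaves=0.005, dead_leaves=0.02, sapwood=0.001, fine_roots=0.010, repro=0.0
        )
    )
    maint_coeff: dict[str, float] = field(  # d-1 at 20 degC
        default_factory=lambda: dict(leaves=0.010, sapwood=0.002, fine_roots=0.008, repro=0.005)
    )
    growth_resp_frac: float = 0.25
    growth_rate: float = 0.25          # d-1 fraction of NSC converted to growth
    target_ratio: dict[str, float] = field(  # g element per g structural C
        default_factory=lambda: dict(N=0.030, P=0.003, K=0.012, Ca=0.006, Mg=0.003, Si=0.015, Na=0.001)
    )
    max_reserve: dict[str, float] = field(  # g element m-2
        default_factory=lambda: dict(N=8.0, P=1.0, K=5.0, Ca=3.0, Mg=1.5, Si=4.0, Na=0.5)
    )
    v_uptake: float = 0.2              # g element (g root C)-1 d-1 at saturation
    k_uptake: float = 10.0             # mol m-3 half-saturation (solution conc)
    t_min: float = 6.0
    t_opt: float = 26.0
    t_max: float = 42.0
    planting_doy: int | None = 120     # None: perennial / always in season
    harvest_doy: int | None = 270
    harvest_export_frac: float = 0.5
    n_fixation: float = 0.0            # g N m-2 d-1 while in season


TRAIT_LIBRARY: dict[str, PlantTraits] = {
    "maize": PlantTraits(),
    "soybean": PlantTraits(
        name="soybean", lue=2.2, planting_doy=140, harvest_doy=280,
        target_ratio=dict(N=0.045, P=0.004, K=0.014, Ca=0.012, Mg=0.003, Si=0.005, Na=0.001),
        max_reserve=dict(N=10.0, P=1.0, K=5.0, Ca=4.0, Mg=1.2, Si=1.5, Na=0.5),
        n_fixation=0.02,
    ),
    "sorghum": PlantTraits(
        name="sorghum", lue=3.0, planting_doy=None, harvest_doy=None,
        target_ratio=dict(N=0.030, P=0.003, K=0.012, Ca=0.005, Mg=0.003, Si=0.020, Na=0.001),
    ),
    "grass": PlantTraits(
        name="grass", lue=1.8, planting_doy=None, harvest_doy=None,
        alloc=dict(leaves=0.45, sapwood=0.05, fine_roots=0.45, repro=0.05),
    ),
}


def get_traits(pft: str, overrides: dict | None = None) -> PlantTraits:
    try:
        traits = TRAIT_LIBRARY[pft]
    except KeyError:
        raise ConfigError(f"unknown plant functional type {pft!r}") from None
    if overrides:
        traits = replace(traits)
        for key, val in overrides.items():
            if not hasattr(traits, key):
                raise ConfigError(f"unknown trait override {key!r}")
            current = getattr(traits, key)
            if isinstance(current, dict):
                current = {**current, **val}
                setattr(traits, key, current)
            else:
                setattr(traits, key, val)
    return traits


@dataclass
class PlantPools:
    """Plant carbon and element state, g m-2."""

    leaves: float = 0.0
    dead_leaves: float = 0.0
    sapwood: float = 0.0
    heartwood: float = 0.0
    fine_roots: float = 0.0
    nsc: float = 0.0
    repro: float = 0.0
    structural: dict[str, float] = field(
        default_factory=lambda: {el: 0.0 for el in PLANT_ELEMENTS}
    )
    reserve: dict[str, float] = field(
        default_factory=lambda: {el: 0.0 for el in PLANT_ELEMENTS}
    )
    anion_content: float = 0.0  # mol_c m-2, passive residual-anion uptake
    starved: bool = False

    @property
    def structural_carbon(self) -> float:
        return self.leaves + self.sapwood + self.heartwood + self.fine_roots + self.repro

    @property
    def total_carbon(self) -> float:
        return self.structural_carbon + self.dead_leaves + self.nsc

    def lai(self, traits: PlantTraits) -> float:
        return self.leaves * traits.sla

    def total_element(self, el: str) -> float:
        return self.structural[el] + self.reserve[el]


def temperature_response(air_temp: float, traits: PlantTraits) -> float:
    """Photosynthesis temperature factor in [0, 1], peaked at t_opt."""
    t, lo, op, hi = air_temp, traits.t_min, traits.t_opt, traits.t_max
    if t <= lo or t >= hi:
        return 0.0
    return max(0.0, (t - lo) * (hi - t) / ((op - lo) * (hi - op)))


def in_season(doy: int, traits: PlantTraits) -> bool:
    if traits.planting_doy is None or traits.harvest_doy is None:
        return True
    return traits.planting_doy <= doy < traits.harvest_doy


def daily_photosynthesis(
    sw_mj: float,
    air_temp: float,
    lai: float,
    water_stress: float,
    nutrient_stress: float,
    traits: PlantTraits,
    active: bool = True,
) -> float:
    """GPP, g C m-2 d-1, from daily shortwave (MJ m-2 d-1) and stresses."""
    if lai < 0:
        raise ParameterError("lai must be >= 0")
    if not (0.0 <= water_stress <= 1.0 and 0.0 <= nutrient_stress <= 1.0):
        raise ParameterError("stresses must lie in [0, 1]")
    if not active:
        return 0.0
    apar = 0.45 * sw_mj * (1.0 - math.exp(-0.5 * lai))
    return traits.lue * apar * temperature_response(air_temp, traits) * water_stress * nutrient_stress


def nutrient_stress(plant: PlantPools, traits: PlantTraits) -> float:
    """Growth limitation from N/P/K stoichiometric satisfaction, in [0.25, 1].

    1 while structural tissue meets its target nutrient content; declines
    (floored at 0.25) when uptake cannot keep pace with growth.
    """
    sc = plant.structural_carbon
    if sc <= 0.0:
        return 1.0
    worst = 1.0
    for el in ("N", "P", "K"):
        target = sc * traits.target_ratio[el]
        if target > 0.0:
            sat = plant.structural[el] / target
            worst = min(worst, max(0.25, min(1.0, sat)))
    return worst


def allocate_respire(
    plant: PlantPools,
    gpp: float,
    soil_temp: float,
    traits: PlantTraits,
    active: bool = True,
    dt: float = 1.0,
) -> tuple[PlantPools, dict[str, float]]:
    """Daily allocation and autotrophic respiration.

    Maintenance respiration (per live tissue, temperature modified) is paid
    from NSC after assimilate arrives; growth only proceeds in season and
    only from remaining NSC, with a fixed growth-respiration surcharge.
    Returns fluxes: r_aut, r_maint, r_growth, growth.
    """
    f_t = min(1.0, 2.0 ** ((soil_temp - 20.0) / 10.0))
    plant.nsc += gpp
    demand = sum(
        traits.maint_coeff[t] * getattr(plant, t) for t in LIVE_TISSUES
    ) * f_t * dt
    paid = min(demand, plant.nsc)
    plant.nsc -= paid
    plant.starved = paid < demand - 1e-12
    growth = 0.0
    r_growth = 0.0
    if active and not plant.starved and plant.nsc > 0.0:
        invest = min(traits.growth_rate * dt, 1.0) * plant.nsc
        growth = invest / (1.0 + traits.growth_resp_frac)
        r_growth = invest - growth
        plant.nsc -= invest
        for tissue, frac in traits.alloc.items():
            setattr(plant, tissue, getattr(plant, tissue) + growth * frac)
    fluxes = dict(
        r_aut=paid + r_growth, r_maint=paid, r_growth=r_growth, growth=growth
    )
    return plant, fluxes


def uptake_suppression(reserve: float, max_reserve: float) -> float:
    """1 below 80% reserve fill, linear to 0 at 100% (continuous, monotone)."""
    if max_reserve <= 0:
        return 0.0
    fill = reserve / max_reserve
    if fill <= 0.8:
        return 1.0
    return max(0.0, (1.0 - fill) / 0.2)


def nutrient_uptake(
    plant: PlantPools,
    solutes: dict[str, float],
    transpiration_m: float,
    water_volume: float,
    traits: PlantTraits,
    dt: float = 1.0,
) -> tuple[PlantPools, dict[str, float]]:
    """Daily element uptake from the soil solution (mutates both states).

    Passive uptake follows the transpiration stream at the solution
    concentration; active transport is Michaelis-Menten in concentration,
    scaled by fine-root mass and structural demand.  Both are multiplied
    by the reserve suppression ramp, capped by the solution mass, and by
    the room left below the reserve maximum.  Na and residual anions are
    passive-only; Al is excluded entirely.
    """
    if transpiration_m < 0:
        raise ParameterError("transpiration must be >= 0")
    uptake: dict[str, float] = {}
    frac_stream = min(transpiration_m / water_volume, 1.0) if water_volume > 0 else 0.0
    for el in PLANT_ELEMENTS:
        if el == "N":
            avail = solutes.get("NH4", 0.0) + solutes.get("NO3", 0.0)
        elif el == "P":
            avail = solutes.get("TPO4", 0.0)
        else:
            avail = solutes.get(el, 0.0)
        if avail <= 0.0:
            uptake[el] = 0.0
            continue
        conc_mol = avail / ATOMIC_MASS["N" if el == "N" else el] / max(water_volume, 1e-9)
        passive = avail * frac_stream
        active = 0.0
        if el != "Na" and plant.fine_roots > 0.0:
            struct_target = plant.structural_carbon * traits.target_ratio[el]
            demand = 1.0
            if struct_target > 0.0:
                demand = min(1.0, max(0.2, (struct_target - plant.structural[el]) / struct_target + 0.2))
            active = (
                traits.v_uptake * plant.fine_roots
                * conc_mol / (traits.k_uptake + conc_mol) * demand * dt
            )
        supp = uptake_suppression(plant.reserve[el], traits.max_reserve[el])
        want = (passive + active) * supp
        struct_need = max(
            0.0, plant.structural_carbon * traits.target_ratio[el] - plant.structural[el]
        )
        room = struct_need + max(0.0, traits.max_reserve[el] - plant.reserve[el])
        got = min(want, avail, room)
        to_struct = min(got, struct_need)
        plant.structural[el] += to_struct
        plant.reserve[el] += got - to_struct
        uptake[el] = got
        if el == "N":
            nh4 = solutes.get("NH4", 0.0)
            share = nh4 / avail
            solutes["NH4"] = nh4 - got * share
            solutes["NO3"] = solutes.get("NO3", 0.0) - got * (1.0 - share)
        elif el == "P":
            solutes["TPO4"] = avail - got
        else:
            solutes[el] = avail - got
    # residual anions: passive stream only
    an = solutes.get("An_r", 0.0)
    an_up = an * frac_stream
    solutes["An_r"] = an - an_up
    plant.anion_content += an_up
    uptake["An_r"] = an_up
    return plant, uptake


def litterfall(
    plant: PlantPools,
    traits: PlantTraits,
    harvest: bool = False,
    dt: float = 1.0,
) -> tuple[PlantPools, dict[str, dict[str, float]], dict[str, float]]:
    """Tissue turnover to the 8 litter pools; optional harvest.

    Element contents leave in proportion to the carbon leaving (tissue
    stoichiometry is uniform across structural pools).  Harvest removes
    ``harvest_export_frac`` of aboveground carbon and elements from the
    system and sends the residue (plus all belowground tissue and
    reserves' litter share) to litter, emptying the plant.
    Returns (plant, litter_in, exported).
    """
    if not 0.0 <= traits.harvest_export_frac <= 1.0:
        raise ConfigError("harvest export fraction must lie in [0, 1]")
    litter: dict[str, dict[str, float]] = {}
    exported = {el: 0.0 for el in PLANT_ELEMENTS}
    exported["C"] = 0.0
    exported["An_r"] = 0.0

    struct_c = plant.structural_carbon
    ratios = {
        el: (plant.structural[el] / struct_c if struct_c > 0.0 else 0.0)
        for el in PLANT_ELEMENTS
    }

    def add(pool: str, c_flux: float, with_elements: bool = True) -> None:
        if c_flux <= 0.0:
            return
        entry = litter.setdefault(pool, {"C": 0.0, **{el: 0.0 for el in PLANT_ELEMENTS}})
        entry["C"] += c_flux
        if with_elements:
            for el in PLANT_ELEMENTS:
                rel = c_flux * ratios[el]
                rel = min(rel, plant.structural[el])
                entry[el] += rel
                plant.structural[el] -= rel

    # ageing turnover
    to_dead = min(traits.turnover["leaves"] * dt, 1.0) * plant.leaves
    plant.leaves -= to_dead
    plant.dead_leaves += to_dead
    shed = min(traits.turnover["dead_leaves"] * dt, 1.0) * plant.dead_leaves
    plant.dead_leaves -= shed
    add("ag_leaf", shed, with_elements=False)  # elements left at senescence
    # senescing leaves carry their stoichiometry into the dead pool;
    # elements are routed to litter when the dead leaves shed
    if to_dead > 0.0:
        entry = litter.setdefault(
            "ag_leaf", {"C": 0.0, **{e: 0.0 for e in PLANT_ELEMENTS}}
        )
        for el in PLANT_ELEMENTS:
            rel = min(to_dead * ratios[el], plant.structural[el])
            plant.structural[el] -= rel
            entry[el] = entry.get(el, 0.0) + rel

    sap_fall = min(traits.turnover["sapwood"] * dt, 1.0) * plant.sapwood
    plant.sapwood -= sap_fall
    add("ag_wood", sap_fall)
    root_fall = min(traits.turnover["fine_roots"] * dt, 1.0) * plant.fine_roots
    plant.fine_roots -= root_fall
    add("bg_fine", root_fall)
    repro_fall = min(traits.turnover["repro"] * dt, 1.0) * plant.repro
    plant.repro -= repro_fall
    add("ag_repro", repro_fall)

    if harvest:
        f_exp = traits.harvest_export_frac
        above = plant.leaves + plant.dead_leaves + plant.sapwood + plant.repro + plant.nsc
        below = plant.fine_roots + plant.heartwood
        exported["C"] += above * f_exp
        add_c = {
            "ag_leaf": (plant.leaves + plant.dead_leaves) * (1.0 - f_exp),
            "ag_wood": plant.sapwood * (1.0 - f_exp),
            "ag_repro": (plant.repro + plant.nsc) * (1.0 - f_exp),
            "bg_root": below,
        }
        add_c = {pool: c for pool, c in add_c.items() if c > 0.0}
        total_c = plant.total_carbon
        for el in PLANT_ELEMENTS:
            tot = plant.structural[el] + plant.reserve[el]
            exp_share = (above * f_exp) / total_c if total_c > 0.0 else 0.0
            exported[el] += tot * exp_share
            rest = tot - tot * exp_share
            # residue elements split over the litter destinations by C
            res_c = sum(add_c.values())
            for pool, c_flux in add_c.items():
                if res_c > 0.0:
                    entry = litter.setdefault(
                        pool, {"C": 0.0, **{e: 0.0 for e in PLANT_ELEMENTS}}
                    )
                    entry[el] = entry.get(el, 0.0) + rest * c_flux / res_c
            plant.structural[el] = 0.0
            plant.reserve[el] = 0.0
        for pool, c_flux in add_c.items():
            if c_flux > 0.0:
                entry = litter.setdefault(
                    pool, {"C": 0.0, **{e: 0.0 for e in PLANT_ELEMENTS}}
                )
                entry["C"] += c_flux
        an_exp = plant.anion_content * (above * f_exp / total_c if total_c > 0.0 else 0.0)
        exported["An_r"] += an_exp
        an_litter = plant.anion_content - an_exp
        plant.anion_content = 0.0
        exported["_An_r_to_soil"] = an_litter  # returned to the soil anion pool
        plant.leaves = plant.dead_leaves = plant.sapwood = 0.0
        plant.heartwood = plant.fine_roots = plant.nsc = plant.repro = 0.0
        plant.starved = False
    return plant, litter, exported
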