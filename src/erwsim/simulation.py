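"""Nested time-stepping orchestrator, spin-up, CDR accounting and outputs.

The operator-split loop runs hourly hydrology; within each hour six
10-minute chemistry sub-steps (weathering release -> solute update ->
exchange equilibrium -> carbonate solve -> pedogenic carbonate -> CO2
transport and DIC leaching) using that hour's water fluxes and the current
day's biology; at each day boundary the daily biology (SOC decomposition,
nutrient budgets, vegetation) runs on the previous day's aggregated
chemistry (time-mean pH, summed transpiration).  Weathering in a sub-step
uses the previous sub-step's pH (explicit coupling, a known O(dt)
splitting error).

Every element (C, N, P, K, Ca, Mg, Na, Si, Al) and water carries a full
ledger: cumulative external inputs and exports are tracked so that
``delta(inventory) = inputs - exports`` can be audited after any run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import biogeochem as bg
from . import chemistry as chem
from . import vegetation as veg
from .config import SimulationConfig
from .constants import ATM_PA, ATOMIC_MASS, M_CO2, R_GAS
from .errors import ConfigError
from .forcing import MeteoForcing
from .hydrology import HydroParams, SoilHydroState, step_soil_water
from .minerals import MineralKinetics, load_mineral_library
from .weathering import FeedstockState, apply_feedstock_event, step_feedstock

log = logging.getLogger(__name__)

SOLUTE_KEYS = ("Ca", "Mg", "K", "Na", "NH4", "NO3", "TPO4", "Si", "Al", "An_r")
EW_ELEMENTS = ("Ca", "Mg", "K", "Na", "Si", "Al", "P", "C")
LEDGER_ELEMENTS = ("C", "N", "P", "K", "Ca", "Mg", "Na", "Si", "Al")

#: element stoichiometry assumed for initial litter stocks, g per g C
_LITTER_INIT_RATIO = dict(N=0.010, P=0.001, K=0.004, Ca=0.003, Mg=0.001, Si=0.004, Na=0.0005)


@dataclass
class SimState:
    """Full model state between steps."""

    hydro: SoilHydroState
    feedstock: FeedstockState
    solutes: dict[str, float]
    exchanger: chem.ExchangeComplex
    ic_tot: float                 # soil gas C + DIC, g C m-2
    carbonate_mineral: float      # pedogenic carbonate, g C m-2
    soc: bg.SOCPools
    nutrients: bg.NutrientPools
    plant: veg.PlantPools
    ph: float = 6.5
    pco2: float = 4.0e-3
    omega_calcite: float = 0.0
    pending_litter: dict = field(default_factory=dict)
    # previous-day aggregates feeding the daily biology
    prev_ph: float = 6.5
    prev_s_eff: float = 0.55
    prev_soil_temp: float = 10.0
    prev_transpiration_m: float = 0.0
    prev_leach_day: float = 0.0


@dataclass
class OutputBundle:
    """Daily state/flux tables, annual summaries and run metadata."""

    daily_state: pd.DataFrame
    daily_fluxes: pd.DataFrame
    annual_summary: pd.DataFrame
    meta: dict
    final_state: SimState
    inventory_initial: dict[str, float]
    inventory_final: dict[str, float]
    inputs: dict[str, float]
    exports: dict[str, float]
    water_balance: dict[str, float]


def _hydro_params(config: SimulationConfig) -> HydroParams:
    s, h = config.site, config.hydrology
    return HydroParams(
        z_a=s.z_a, porosity=s.porosity, field_capacity=s.field_capacity,
        wilting_point=s.wilting_point, k_s=s.k_s, b_exponent=s.b_exponent,
        pt_alpha=h.pt_alpha, albedo=h.albedo, snow_ddf=h.snow_ddf, lw_loss=h.lw_loss,
        damping_days=h.damping_days, soil_temp_floor=h.soil_temp_floor,
    )


def initial_state(config: SimulationConfig, forcing: MeteoForcing) -> SimState:
    """Build the t=0 state from the config's initial pools."""
    site = config.site
    t0 = float(forcing.data["air_temp_C"].iloc[0])
    hydro = SoilHydroState(s_eff=config.initial.s_eff, soil_temp=t0)

    solutes = {k: float(config.initial.solutes.get(k, 0.0)) for k in SOLUTE_KEYS}
    exchanger = chem.ExchangeComplex(
        cec=site.cec,
        fractions=dict(config.initial.exchange_fractions),
        selectivities=dict(
            Ca=1.0, Mg=config.chemistry.k_mg, K=config.chemistry.k_k,
            Na=config.chemistry.k_na, H=config.chemistry.k_h,
        ),
    )

    soc = bg.SOCPools(**{k: float(v) for k, v in config.initial.soc.items()})
    for name, c_mass in config.initial.litter.items():
        pool = soc.litter[name]
        pool["C"] = float(c_mass)
        for el, ratio in _LITTER_INIT_RATIO.items():
            pool[el] = float(c_mass) * ratio

    nut = bg.NutrientPools()
    for key, val in config.initial.nutrients.items():
        if key.startswith("org_"):
            nut.org[key[4:]] = float(val)
        elif key.endswith("_primary"):
            nut.primary[key[:-8]] = float(val)
        elif key.endswith("_secondary"):
            nut.secondary[key[:-10]] = float(val)
        else:
            raise ConfigError(f"unknown initial nutrient pool {key!r}")
    for el in bg.ORG_ELEMENTS:  # modest organic stocks when unspecified
        if nut.org.get(el, 0.0) == 0.0 and el not in ("N", "P"):
            nut.org[el] = {"K": 40.0, "Ca": 60.0, "Mg": 15.0, "Si": 50.0, "Na": 5.0}[el]

    # inorganic carbon: soil gas at the configured ppm + equilibrium DIC
    v_w = hydro.water_volume(_hydro_params(config))
    v_air = site.porosity * (1.0 - hydro.s_eff) * site.z_a
    pco2 = config.chemistry.soil_co2_init_ppm * 1e-6
    t_k = t0 + 273.15
    gas_c = pco2 * ATM_PA / (R_GAS * t_k) * ATOMIC_MASS["C"] * v_air
    alk0 = chem.alkalinity(solutes, v_w)
    try:
        ph0, co2aq, hco3, co3 = chem.solve_carbonate_system(alk0, pco2, t0)
        dic = (co2aq + hco3 + co3) * v_w * ATOMIC_MASS["C"]
    except chem.ChemistryError:
        ph0, dic = 6.5, 0.0

    return SimState(
        hydro=hydro,
        feedstock=FeedstockState(),
        solutes=solutes,
        exchanger=exchanger,
        ic_tot=gas_c + dic,
        carbonate_mineral=0.0,
        soc=soc,
        nutrients=nut,
        plant=veg.PlantPools(),
        ph=ph0,
        pco2=pco2,
        prev_ph=ph0,
        prev_s_eff=hydro.s_eff,
        prev_soil_temp=t0,
    )


def element_inventory(
    state: SimState, library: dict[str, MineralKinetics], config: SimulationConfig
) -> dict[str, float]:
    """Whole-system element inventory, g m-2 (An_r in mol_c m-2)."""
    inv = {el: 0.0 for el in LEDGER_ELEMENTS}
    inv["An_r"] = 0.0
    soc, nut, plant = state.soc, state.nutrients, state.plant

    inv["C"] = (
        soc.total_carbon() + plant.total_carbon + state.ic_tot + state.carbonate_mineral
    )
    for cohort in state.feedstock.cohorts:  # carbonate feedstock carries C
        mineral = library[cohort.mineral]
        moles = cohort.mass * 1000.0 / mineral.molar_mass
        for el, nu in mineral.stoichiometry.items():
            inv[el] = inv.get(el, 0.0) + moles * nu * ATOMIC_MASS[el]

    for el in LEDGER_ELEMENTS:
        if el == "C":
            continue
        total = 0.0
        total += nut.org.get(el, 0.0)
        total += nut.primary.get(el, 0.0)
        total += nut.secondary.get(el, 0.0)
        total += soc.litter_element(el) if el in bg.ORG_ELEMENTS else 0.0
        if el in veg.PLANT_ELEMENTS:
            total += plant.total_element(el)
        if el == "N":
            total += state.solutes["NH4"] + state.solutes["NO3"]
        elif el == "P":
            total += state.solutes["TPO4"]
        else:
            total += state.solutes.get(el, 0.0)
        if el in chem.BASE_CATIONS:
            total += (
                state.exchanger.fractions[el] * state.exchanger.cec
                / {"Ca": 2, "Mg": 2, "K": 1, "Na": 1}[el] * ATOMIC_MASS[el]
            )
        if el == "Ca":
            total += state.carbonate_mineral / ATOMIC_MASS["C"] * ATOMIC_MASS["Ca"]
        inv[el] += total
    inv["An_r"] = state.solutes["An_r"] + plant.anion_content
    return inv


def _pft_for_year(config: SimulationConfig, year_index: int) -> str:
    return config.vegetation.rotation.get(year_index, config.vegetation.pft)


def run_simulation(
    config: SimulationConfig,
    forcing: MeteoForcing,
    start_state: SimState | None = None,
    apply_feedstock: bool = True,
) -> OutputBundle:
    """Run the coupled model over the forcing record.

    Identical (config, forcing, start_state) give bit-identical outputs:
    the simulation itself is deterministic (all randomness lives in the
    forcing generator).
    """
    site = config.site
    hp = _hydro_params(config)
    library = load_mineral_library()
    params = bg.load_biogeochem_params(config.biogeochem_overrides or None)
    chem_cfg = config.chemistry

    # clip the forcing to the scheduled window (whole days)
    ts_all = pd.to_datetime(forcing.data["timestamp"])
    window = (ts_all >= config.schedule.start) & (
        ts_all <= config.schedule.end + pd.Timedelta(hours=23)
    )
    df = forcing.data[window].reset_index(drop=True)
    n_days = len(df) // 24
    if n_days == 0:
        raise ConfigError(
            "forcing record does not cover the scheduled simulation window"
        )
    df = df.iloc[: n_days * 24]
    n_hours = len(df)
    temps = df["air_temp_C"].to_numpy(float)
    precs = df["precip_mm"].to_numpy(float)
    sws = df["sw_Wm2"].to_numpy(float)
    co2s = df["co2_ppm"].to_numpy(float)
    stamps = pd.to_datetime(df["timestamp"]).to_numpy()
    day_dates = pd.to_datetime(stamps[::24]).normalize()
    sw_mj_day = sws[: n_days * 24].reshape(n_days, 24).sum(axis=1) * 3600.0 / 1e6
    temp_day = temps[: n_days * 24].reshape(n_days, 24).mean(axis=1)

    state = copy.deepcopy(start_state) if start_state is not None else initial_state(config, forcing)
    inv0 = element_inventory(state, library, config)
    inputs = {el: 0.0 for el in list(LEDGER_ELEMENTS) + ["An_r"]}
    exports = {el: 0.0 for el in list(LEDGER_ELEMENTS) + ["An_r"]}

    fert_by_date: dict = {}
    for fert in config.external.fertilisation:
        fert_by_date.setdefault(pd.Timestamp(fert["date"]).normalize(), []).append(fert)
    events_by_date: dict = {}
    if apply_feedstock:
        for ev in config.feedstock_events:
            events_by_date.setdefault(pd.Timestamp(ev.date).normalize(), []).append(ev)

    water = dict(precip=0.0, runoff=0.0, evap=0.0, transp=0.0, leak=0.0,
                 storage0=state.hydro.s_eff * hp.capacity_mm + state.hydro.snow_mm)

    rows_state: list[dict] = []
    rows_flux: list[dict] = []
    traits = veg.get_traits(
        _pft_for_year(config, 0), config.vegetation.trait_overrides or None
    )
    year0 = pd.Timestamp(day_dates[0]).year

    for d in range(n_days):
        date = pd.Timestamp(day_dates[d])
        doy = min(date.dayofyear, 365)
        year_index = date.year - year0
        traits = veg.get_traits(
            _pft_for_year(config, year_index), config.vegetation.trait_overrides or None
        )
        active = veg.in_season(doy, traits)

        # --- feedstock and fertiliser events
        for ev in events_by_date.get(date, []):
            apply_feedstock_event(state.feedstock, ev, library)
            for mineral_name, frac in ev.mineral_fractions.items():
                mineral = library[mineral_name]
                moles = ev.rate * frac * 1000.0 / mineral.molar_mass
                for el, nu in mineral.stoichiometry.items():
                    inputs[el] = inputs.get(el, 0.0) + moles * nu * ATOMIC_MASS[el]
        ext_n = config.external.n_deposition
        ext_p = config.external.p_deposition
        for fert in fert_by_date.get(date, []):
            ext_n += float(fert.get("n", 0.0))
            ext_p += float(fert.get("p", 0.0))
        if active and traits.n_fixation > 0.0:
            ext_n += traits.n_fixation

        # --- planting
        plant_today = (
            traits.planting_doy is not None and doy == traits.planting_doy
        ) or (traits.planting_doy is None and d == 0 and state.plant.total_carbon == 0.0)
        if plant_today and state.plant.total_carbon == 0.0:
            seed = config.vegetation.seed_carbon
            state.plant.leaves += 0.3 * seed
            state.plant.fine_roots += 0.2 * seed
            state.plant.nsc += 0.5 * seed
            inputs["C"] += seed
            for el in veg.PLANT_ELEMENTS:
                struct = 0.5 * seed * traits.target_ratio[el]
                res = 0.25 * traits.max_reserve[el]
                state.plant.structural[el] += struct
                state.plant.reserve[el] += res
                inputs[el] = inputs.get(el, 0.0) + struct + res

        # --- daily biology on yesterday's aggregated chemistry
        env = bg.env_modifiers(state.prev_soil_temp, state.prev_s_eff, state.prev_ph, params)
        myco_c = min(0.01 * state.plant.nsc, state.plant.nsc)
        state.plant.nsc -= myco_c
        state.soc, socfx = bg.step_soc(
            state.soc, env, state.pending_litter or None, params, myco_c_supply=myco_c
        )
        state.pending_litter = {}
        immob_n = (socfx["growth"] - socfx.get("mortality", 0.0)) / params["cn_microbe"]
        immob_p = (socfx["growth"] - socfx.get("mortality", 0.0)) / params["cp_microbe"]
        som_rel = bg.som_element_release(state.nutrients, state.soc, socfx["decomp_c"])
        leach_day = state.prev_leach_day

        nfx = bg.step_nitrogen(
            state.solutes, state.nutrients, env, params,
            socfx["litter_release_N"], som_rel["N"], immob_n, leach_day,
            ext_n, state.prev_s_eff, state.prev_ph,
        )
        inputs["N"] += ext_n
        exports["N"] += nfx["n_leached"] + nfx["n_org_leach"] + nfx["n_volatilised"] + nfx["n_denitrified"]
        pfx = bg.step_phosphorus(
            state.solutes, state.nutrients, env, params,
            socfx["litter_release_P"], som_rel["P"], immob_p, leach_day, ext_p,
        )
        inputs["P"] += ext_p
        exports["P"] += pfx["p_leached"] + pfx["p_org_leach"]
        ext_cat = dict(
            K=config.external.k_deposition, Ca=config.external.ca_deposition,
            Mg=config.external.mg_deposition,
        )
        cfx = bg.step_cations(
            state.solutes, state.nutrients, params,
            {x: socfx[f"litter_release_{x}"] for x in ("K", "Ca", "Mg")},
            som_rel, leach_day, ext_cat,
        )
        for x in ("K", "Ca", "Mg"):
            inputs[x] += ext_cat[x]
            exports[x] += cfx[f"{x}_leached"] + cfx[f"{x}_org_leach"]
        ext_misc = dict(
            Si=0.0, Na=config.external.na_deposition, Al=0.0,
            An_r=config.external.anion_deposition,
        )
        sfx = bg.step_si_na_al_anions(
            state.solutes, state.nutrients, params,
            {x: socfx[f"litter_release_{x}"] for x in ("Si", "Na")},
            som_rel, leach_day, ext_misc,
        )
        inputs["Na"] += ext_misc["Na"]
        inputs["An_r"] += ext_misc["An_r"]
        exports["Si"] += sfx["Si_leached"] + sfx["Si_org_leach"]
        exports["Na"] += sfx["Na_leached"] + sfx["Na_org_leach"]
        exports["Al"] += sfx["Al_leached"]
        exports["An_r"] += sfx["An_r_leached"]

        # --- vegetation
        lai = state.plant.lai(traits)
        # plant water stress on a gentler s_eff ramp than the bucket's ET
        # limit: crops bridge dry spells with water below the lumped layer
        h_cfg = config.hydrology
        beta = (state.prev_s_eff - h_cfg.s_wilt_stress) / (
            h_cfg.s_star_stress - h_cfg.s_wilt_stress
        )
        water_stress = min(1.0, max(0.0, beta))
        n_stress = veg.nutrient_stress(state.plant, traits)
        gpp = veg.daily_photosynthesis(
            sw_mj_day[d], temp_day[d], lai, water_stress, n_stress, traits, active
        )
        inputs["C"] += gpp
        state.plant, vfx = veg.allocate_respire(
            state.plant, gpp, state.prev_soil_temp, traits, active
        )
        v_w_now = state.hydro.water_volume(hp)
        state.plant, upfx = veg.nutrient_uptake(
            state.plant, state.solutes, state.prev_transpiration_m, v_w_now, traits
        )
        harvest_today = traits.harvest_doy is not None and doy == traits.harvest_doy
        state.plant, litter_in, harvested = veg.litterfall(
            state.plant, traits, harvest=harvest_today
        )
        state.pending_litter = litter_in
        exports["C"] += harvested.get("C", 0.0)
        for el in veg.PLANT_ELEMENTS:
            exports[el] = exports.get(el, 0.0) + harvested.get(el, 0.0)
        exports["An_r"] += harvested.get("An_r", 0.0)
        state.solutes["An_r"] += harvested.get("_An_r_to_soil", 0.0)

        r_het = socfx["r_het"]
        r_aut = vfx["r_aut"]
        resp_substep = (r_het + r_aut) / 144.0

        # --- hourly hydrology + 10-min chemistry
        day_ph_sum = 0.0
        day_transp = 0.0
        day_leach_m = 0.0
        day_seff_sum = 0.0
        day_stemp_sum = 0.0
        day_ew = {el: 0.0 for el in EW_ELEMENTS}
        day_efflux = 0.0
        day_dic_leach = 0.0
        day_w_carb = 0.0
        day_rain_dic = 0.0

        for h in range(24):
            i = d * 24 + h
            state.hydro, wf = step_soil_water(
                state.hydro, temps[i], precs[i], sws[i], lai, hp
            )
            water["precip"] += precs[i]
            water["runoff"] += wf.runoff
            water["evap"] += wf.evaporation
            water["transp"] += wf.transpiration
            water["leak"] += wf.leakage
            day_transp += wf.transpiration / 1000.0
            day_seff_sum += state.hydro.s_eff
            day_stemp_sum += state.hydro.soil_temp

            v_w = max(state.hydro.water_volume(hp), 1e-6)
            v_air = max(site.porosity * (1.0 - state.hydro.s_eff) * site.z_a, 1e-6)
            leach_sub = (wf.leakage / 1000.0) / v_w / 6.0
            day_leach_m += wf.leakage / 1000.0
            infil_sub = (wf.infiltration / 1000.0) / 6.0
            stemp = state.hydro.soil_temp
            s_eff = state.hydro.s_eff
            t_k = stemp + 273.15
            c_atm = co2s[i] * 1e-6 * ATM_PA / (R_GAS * t_k) * ATOMIC_MASS["C"]
            k_eff = chem.co2_efflux_coefficient(stemp, site.porosity, s_eff, site.z_a)

            for _ in range(6):
                # 1. weathering at the previous sub-step's pH
                if state.feedstock.cohorts:
                    ph_w = chem_cfg.freeze_ph if chem_cfg.freeze_ph is not None else state.ph
                    rel = step_feedstock(
                        state.feedstock, library, ph_w, stemp, s_eff,
                        {"calcite": state.omega_calcite}, config.f_d,
                    )
                    for el in ("Ca", "Mg", "K", "Na", "Si", "Al"):
                        state.solutes[el] += rel[el]
                    state.solutes["TPO4"] += rel["P"]
                    state.ic_tot += rel["C"]
                    for el in EW_ELEMENTS:
                        day_ew[el] += rel[el]
                # 2. respiration + rain DIC
                state.ic_tot += resp_substep + infil_sub * chem_cfg.dic_rain
                day_rain_dic += infil_sub * chem_cfg.dic_rain
                # 3+4. self-consistent exchange + carbonate solve
                part = chem.coupled_exchange_carbonate(
                    state.solutes, state.exchanger, state.ic_tot, stemp,
                    v_air, v_w, ph_guess=state.ph, pco2_guess=state.pco2,
                )
                state.ph = part["ph"]
                state.pco2 = part["pco2"]
                # 5. pedogenic carbonate
                ca_mol_l = state.solutes["Ca"] / ATOMIC_MASS["Ca"] / v_w / 1000.0
                w_carb = chem.carbonate_mineral_step(
                    ca_mol_l, part["co3"] / 1000.0, state.carbonate_mineral,
                    chem_cfg.k_p, 600.0, stemp,
                )
                if w_carb < 0.0:  # precipitation limited by DIC and Ca
                    w_carb = -min(-w_carb, part["dic"],
                                  state.solutes["Ca"] / ATOMIC_MASS["Ca"] * ATOMIC_MASS["C"])
                state.carbonate_mineral -= w_carb
                state.ic_tot += w_carb
                state.solutes["Ca"] += w_carb / ATOMIC_MASS["C"] * ATOMIC_MASS["Ca"]
                day_w_carb += w_carb
                state.omega_calcite = chem.calcite_saturation_ratio(
                    ca_mol_l, part["co3"] / 1000.0, stemp
                )
                # 6. CO2 efflux and DIC leaching
                c_soil = part["gas_c"] / v_air
                efflux = k_eff * (c_soil - c_atm) * 600.0
                efflux = min(efflux, part["gas_c"]) if efflux > 0 else efflux
                lk_dic = min(part["dic"] * leach_sub, part["dic"])
                state.ic_tot -= efflux + lk_dic
                day_efflux += efflux
                day_dic_leach += lk_dic
                day_ph_sum += state.ph

        inputs["C"] += day_rain_dic
        exports["C"] += day_efflux + day_dic_leach

        # --- update previous-day aggregates for tomorrow's biology
        state.prev_ph = day_ph_sum / 144.0
        state.prev_s_eff = day_seff_sum / 24.0
        state.prev_soil_temp = day_stemp_sum / 24.0
        state.prev_transpiration_m = day_transp
        v_w_end = max(state.hydro.water_volume(hp), 1e-6)
        state.prev_leach_day = min(day_leach_m / v_w_end, 1.0)

        # --- bookkeeping rows
        re_total = r_aut + r_het
        nee = re_total - gpp
        mol_ca = day_ew["Ca"] / ATOMIC_MASS["Ca"]
        mol_mg = day_ew["Mg"] / ATOMIC_MASS["Mg"]
        potential_cdr = (2.0 * mol_ca + 2.0 * mol_mg) * M_CO2
        if chem_cfg.include_monovalent_cdr:
            potential_cdr += (
                day_ew["K"] / ATOMIC_MASS["K"] + day_ew["Na"] / ATOMIC_MASS["Na"]
            ) * M_CO2
        potential_cdr_mono = (
            day_ew["K"] / ATOMIC_MASS["K"] + day_ew["Na"] / ATOMIC_MASS["Na"]
        ) * M_CO2
        effective_cdr = day_dic_leach * M_CO2 / ATOMIC_MASS["C"]

        rows_state.append(dict(
            date=date, ph=state.prev_ph, s_eff=state.prev_s_eff,
            soil_temp=state.prev_soil_temp,
            alk=chem.alkalinity(state.solutes, v_w_end),
            base_saturation=chem.base_saturation(state.exchanger),
            soil_gas_pco2=state.pco2, ic_tot=state.ic_tot,
            carbonate_mineral=state.carbonate_mineral,
            feedstock_mass=state.feedstock.total_mass,
            soc_total=state.soc.total_carbon(), plant_c=state.plant.total_carbon,
            lai=state.plant.lai(traits),
            **{f"sol_{k}": state.solutes[k] for k in SOLUTE_KEYS},
        ))
        rows_flux.append(dict(
            date=date, gpp=gpp, r_aut=r_aut, r_het=r_het, re=re_total, nee=nee,
            co2_efflux=day_efflux, dic_leach=day_dic_leach,
            w_camgco3=day_w_carb, cue=socfx["cue"],
            potential_cdr=potential_cdr, potential_cdr_monovalent=potential_cdr_mono,
            effective_cdr=effective_cdr,
            transpiration_mm=day_transp * 1000.0, leach_mm=day_leach_m * 1000.0,
            **{f"ew_{el}": day_ew[el] for el in EW_ELEMENTS},
            **{f"uptake_{el}": upfx.get(el, 0.0) for el in veg.PLANT_ELEMENTS},
        ))

    water["storage1"] = state.hydro.s_eff * hp.capacity_mm + state.hydro.snow_mm
    water["residual"] = (
        water["storage1"] - water["storage0"]
        - (water["precip"] - water["runoff"] - water["evap"]
           - water["transp"] - water["leak"])
    )

    daily_state = pd.DataFrame(rows_state)
    daily_fluxes = pd.DataFrame(rows_flux)
    annual = compute_annual_summary(daily_fluxes)
    meta = dict(
        config_hash=config_hash(config),
        n_days=n_days,
        start=str(pd.Timestamp(day_dates[0]).date()),
        end=str(pd.Timestamp(day_dates[-1]).date()),
        version="0.1.0",
    )
    inv1 = element_inventory(state, library, config)
    return OutputBundle(
        daily_state=daily_state, daily_fluxes=daily_fluxes, annual_summary=annual,
        meta=meta, final_state=state, inventory_initial=inv0, inventory_final=inv1,
        inputs=inputs, exports=exports, water_balance=water,
    )


def ledger_residuals(bundle: OutputBundle) -> dict[str, float]:
    """Relative element-ledger closure errors: |dInv - (in - out)| / scale."""
    out = {}
    for el in list(LEDGER_ELEMENTS) + ["An_r"]:
        d_inv = bundle.inventory_final[el] - bundle.inventory_initial[el]
        net = bundle.inputs.get(el, 0.0) - bundle.exports.get(el, 0.0)
        scale = max(
            abs(bundle.inventory_initial[el]), abs(bundle.inventory_final[el]),
            abs(bundle.inputs.get(el, 0.0)), 1e-9,
        )
        out[el] = abs(d_inv - net) / scale
    return out


def compute_cdr(daily_fluxes: pd.DataFrame) -> pd.DataFrame:
    """Annual potential/effective CDR totals, t CO2 ha-1 yr-1.

    Potential CDR counts the CO2 equivalent of weathering-released Ca + Mg
    (2 mol CO2 per mol divalent cation); the monovalent contribution is
    reported separately as a diagnostic.  Effective CDR is the DIC
    leaching flux expressed as CO2.  1 g m-2 = 0.01 t ha-1.
    """
    df = daily_fluxes.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    g = df.groupby("year")[
        ["potential_cdr", "potential_cdr_monovalent", "effective_cdr"]
    ].sum()
    return (g * 0.01).rename(columns=lambda c: f"{c}_tCO2_ha")


def compute_annual_summary(daily_fluxes: pd.DataFrame) -> pd.DataFrame:
    df = daily_fluxes.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year
    sums = df.groupby("year")[
        ["gpp", "r_aut", "r_het", "re", "nee", "co2_efflux", "dic_leach",
         "potential_cdr", "effective_cdr", "transpiration_mm", "leach_mm"]
        + [f"ew_{el}" for el in EW_ELEMENTS]
    ].sum()
    cdr = compute_cdr(daily_fluxes)
    return sums.join(cdr)


def spin_up(
    config: SimulationConfig, forcing: MeteoForcing, n_cycles: int
) -> tuple[SimState, dict[str, float]]:
    """Recycle the forcing with no feedstock until pools settle.

    Returns the end state and the per-pool relative drift over the final
    cycle; warns when any pool still drifts by more than 1%.
    """
    if n_cycles < 1:
        raise ConfigError("spin-up requires n_cycles >= 1")
    state = initial_state(config, forcing)
    prev_snapshot = _spinup_snapshot(state)
    drift: dict[str, float] = {}
    for cycle in range(n_cycles):
        bundle = run_simulation(config, forcing, start_state=state, apply_feedstock=False)
        state = bundle.final_state
        snap = _spinup_snapshot(state)
        drift = {
            k: abs(snap[k] - prev_snapshot[k]) / max(abs(snap[k]), 1e-9)
            for k in snap
        }
        prev_snapshot = snap
    not_converged = {k: v for k, v in drift.items() if v > 0.01}
    if not_converged:
        log.warning("spin-up not converged (>1%% drift): %s", not_converged)
    return state, drift


def _spinup_snapshot(state: SimState) -> dict[str, float]:
    snap = dict(
        soc=state.soc.total_carbon(),
        ph=state.ph,
        ic_tot=state.ic_tot,
    )
    for x in chem.BASE_CATIONS:
        snap[f"sol_{x}"] = state.solutes[x]
        snap[f"exch_{x}"] = state.exchanger.fractions[x]
    return snap


def config_hash(config: SimulationConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(bundle: OutputBundle, out_dir, seed: int | None = None) -> list:
    """Write daily tables, the annual summary and run metadata.

    Re-running with identical inputs produces byte-identical files; a
    round-trip read reproduces the in-memory values to printed precision.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("daily_state.csv", bundle.daily_state),
        ("daily_fluxes.csv", bundle.daily_fluxes),
        ("annual_summary.csv", bundle.annual_summary.reset_index()),
    ):
        path = out / name
        df.to_csv(path, index=False, float_format="%.12g")
        paths.append(path)
    meta = dict(bundle.meta)
    if seed is not None:
        meta["seed"] = seed
    meta["water_balance_residual_mm"] = bundle.water_balance["residual"]
    meta["ledger_residuals"] = ledger_residuals(bundle)
    meta_path = out / "run_meta.txt"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    paths.append(meta_path)
    return paths
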