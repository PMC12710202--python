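"""Carbonate-system equilibrium, alkalinity, cation exchange, pedogenic carbonate.

All solutions are treated as ideal (unit activity coefficients): soil
porewater at the concentrations of interest is dilute.  The open-system
carbonate charge balance

    ALK = [HCO3-] + 2[CO3--] + [OH-] - [H+],   [H2CO3*] = K_H * pCO2

reduces exactly to a cubic in h = [H+] (mol/L),

    h^3 + ALK*h^2 - (K_H*K1*pCO2 + Kw)*h - 2*K_H*K1*K2*pCO2 = 0,

which has exactly one positive root; it is found by bracketed Newton with
a bisection fallback inside pH [2, 12].  Equilibrium constants are
temperature-corrected by van 't Hoff.

Cation exchange is a Gaines-Thomas equilibrium over Ca, Mg, K, Na (plus an
optional exchangeable-acidity H+ species whose solution activity is set by
the ambient pH).  With equivalent fractions E_j and activities a_j (mol/L),
the pairwise relations collapse onto a single exchange potential u:

    E_j = (k_j * u)**(z_j/2) * a_j,      k_Ca = 1 (reference)

so that sum(E_j) = 1 is a quadratic in sqrt(u) solved in closed form; a
damped fixed-point iteration then enforces exact per-cation mass
conservation between solution and exchanger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import (
    ATM_PA,
    ATOMIC_MASS,
    CHARGE,
    D0_CO2,
    DH_K1,
    DH_K2,
    DH_KH,
    DH_KSP_CALCITE,
    DH_KW,
    LOG10_K1,
    LOG10_K2,
    LOG10_KH,
    LOG10_KSP_CALCITE,
    LOG10_KW,
    R_GAS,
    vant_hoff,
)
from .errors import ChemistryError, ParameterError

BASE_CATIONS = ("Ca", "Mg", "K", "Na")


def carbonate_constants(temp_c: float) -> tuple[float, float, float, float]:
    """(K_H, K1, K2, Kw) at ``temp_c``; mol/L basis, K_H in mol/(L atm)."""
    return (
        vant_hoff(LOG10_KH, DH_KH, temp_c),
        vant_hoff(LOG10_K1, DH_K1, temp_c),
        vant_hoff(LOG10_K2, DH_K2, temp_c),
        vant_hoff(LOG10_KW, DH_KW, temp_c),
    )


def calcite_ksp(temp_c: float) -> float:
    return vant_hoff(LOG10_KSP_CALCITE, DH_KSP_CALCITE, temp_c)


def alkalinity(solutes: dict[str, float], water_volume: float) -> float:
    """Porewater alkalinity, mol_c m-3.

    ``ALK = 2[Ca] + 2[Mg] + [K] + [Na] + [NH4] - [NO3] - [An_r] - [TPO4]``
    with concentrations in mol m-3 of pore water.  Solute masses are g m-2
    (NH4/NO3 as g N, TPO4 as g P); ``An_r`` is carried directly in
    mol_c m-2.  Negative alkalinity is a valid acidic state.
    """
    if water_volume <= 0:
        raise ParameterError("water_volume must be > 0")
    eq = (
        2.0 * solutes.get("Ca", 0.0) / ATOMIC_MASS["Ca"]
        + 2.0 * solutes.get("Mg", 0.0) / ATOMIC_MASS["Mg"]
        + solutes.get("K", 0.0) / ATOMIC_MASS["K"]
        + solutes.get("Na", 0.0) / ATOMIC_MASS["Na"]
        + solutes.get("NH4", 0.0) / ATOMIC_MASS["N"]
        - solutes.get("NO3", 0.0) / ATOMIC_MASS["N"]
        - solutes.get("An_r", 0.0)
        - solutes.get("TPO4", 0.0) / ATOMIC_MASS["P"]
    )
    return eq / water_volume


def _carbonate_cubic_root(
    alk_molm3: float, pco2_atm: float, temp_c: float, h_guess: float | None = None
) -> tuple[float, float, float, float, float]:
    """Positive root h (mol/L) of the open-system charge balance + constants."""
    kh, k1, k2, kw = carbonate_constants(temp_c)
    a = alk_molm3 / 1000.0
    b = kh * k1 * pco2_atm + kw
    c = 2.0 * kh * k1 * k2 * pco2_atm

    def f(h: float) -> float:
        return ((h + a) * h - b) * h - c

    lo, hi = 1.0e-13, 1.0e-1
    # the cubic always has exactly one positive root; expand if needed
    expand = 0
    while f(lo) > 0.0 and expand < 8:
        lo *= 1e-1
        expand += 1
    while f(hi) < 0.0 and expand < 16:
        hi *= 1e1
        expand += 1
    if f(lo) > 0.0 or f(hi) < 0.0:
        raise ChemistryError(
            f"no charge-balance root in the pH bracket "
            f"(ALK={alk_molm3} mol/m3, pCO2={pco2_atm} atm, T={temp_c} C)"
        )
    h = h_guess if h_guess and lo < h_guess < hi else 1.0e-7
    for _ in range(200):
        fh = f(h)
        if fh > 0.0:
            hi = h
        else:
            lo = h
        dfh = (3.0 * h + 2.0 * a) * h - b
        step_ok = dfh != 0.0
        if step_ok:
            h_new = h - fh / dfh
            step_ok = lo < h_new < hi
        if not step_ok:
            h_new = 0.5 * (lo + hi)
        if abs(h_new - h) <= 1e-16 * h:
            h = h_new
            break
        h = h_new
    return h, kh, k1, k2, kw


def solve_carbonate_system(
    alk: float, pco2: float, temp_c: float = 25.0, h_guess: float | None = None
) -> tuple[float, float, float, float]:
    """Open-system equilibrium with a fixed soil-air CO2 reservoir.

    Parameters: alkalinity (mol_c m-3), soil pCO2 (atm), temperature (degC).
    Returns ``(pH, [H2CO3*], [HCO3-], [CO3--])`` with concentrations in
    mol m-3.
    """
    if pco2 <= 0:
        raise ParameterError("pCO2 must be > 0")
    h, kh, k1, k2, _ = _carbonate_cubic_root(alk, pco2, temp_c, h_guess)
    co2aq = kh * pco2
    hco3 = k1 * co2aq / h
    co3 = k2 * hco3 / h
    return -math.log10(h), co2aq * 1000.0, hco3 * 1000.0, co3 * 1000.0


def dic_speciation_fractions(ph: float, temp_c: float = 25.0) -> tuple[float, float, float]:
    """Fractions of DIC as (H2CO3*, HCO3-, CO3--); they sum to 1."""
    _, k1, k2, _ = carbonate_constants(temp_c)
    h = 10.0 ** (-ph)
    denom = 1.0 + k1 / h + k1 * k2 / h**2
    f0 = 1.0 / denom
    f1 = f0 * k1 / h
    f2 = f1 * k2 / h
    return f0, f1, f2


def equilibrate_inorganic_carbon(
    ic_tot: float,
    alk: float,
    temp_c: float,
    v_air: float,
    v_w: float,
    pco2_guess: float = 4.0e-4,
) -> dict[str, float]:
    """Partition total inorganic C between soil air and porewater.

    Finds the pCO2 at which the gas-phase C (ideal gas in air volume
    ``v_air`` m3/m2) plus the DIC in equilibrium with it (water volume
    ``v_w``) equals ``ic_tot`` (g C m-2), with the pH from the alkalinity
    charge balance.  Returns pco2 (atm), ph, gas_c/dic (g C m-2) and the
    mol/L carbonate speciation.
    """
    if ic_tot <= 0.0:
        return dict(pco2=1e-12, ph=7.0, gas_c=0.0, dic=0.0, co2aq=0.0, hco3=0.0, co3=0.0)
    t_k = temp_c + 273.15
    gas_coeff = ATM_PA / (R_GAS * t_k) * ATOMIC_MASS["C"] * v_air  # g C per atm
    h_guess = None

    def masses(pco2: float) -> tuple[float, float, float, float, float, float]:
        nonlocal h_guess
        h, kh, k1, k2, _ = _carbonate_cubic_root(alk, pco2, temp_c, h_guess)
        h_guess = h
        co2aq = kh * pco2
        hco3 = k1 * co2aq / h
        co3 = k2 * hco3 / h
        dic = (co2aq + hco3 + co3) * 1000.0 * v_w * ATOMIC_MASS["C"]
        return gas_coeff * pco2 + dic, h, co2aq, hco3, co3, dic

    # bracketed secant in log10(pCO2); total mass is monotone in pCO2
    lo, hi = math.log10(1.0e-10), math.log10(0.95)
    tol = 1e-12 * max(ic_tot, 1e-9)
    x = math.log10(min(max(pco2_guess, 2.0e-10), 0.5))
    total, h, co2aq, hco3, co3, dic = masses(10.0**x)
    err = total - ic_tot
    x_prev, err_prev = None, None
    for _ in range(200):
        if abs(err) <= tol:
            break
        if err > 0:
            hi = x
        else:
            lo = x
        if hi - lo < 1e-14:
            break
        if err_prev is not None and err_prev != err:
            x_new = x - err * (x - x_prev) / (err - err_prev)
        else:
            x_new = None
        if x_new is None or not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        x_prev, err_prev = x, err
        x = x_new
        total, h, co2aq, hco3, co3, dic = masses(10.0**x)
        err = total - ic_tot
    else:
        raise ChemistryError(
            f"inorganic-C partitioning did not converge "
            f"(ic_tot={ic_tot}, alk={alk}, T={temp_c}, v_air={v_air}, v_w={v_w})"
        )
    if abs(err) > 1e-6 * max(ic_tot, 1.0):
        raise ChemistryError(
            f"inorganic-C partitioning mass residual {err:.3e} g C m-2 "
            f"(ic_tot={ic_tot}, alk={alk}, T={temp_c})"
        )
    x = 10.0**x
    return dict(
        pco2=x,
        ph=-math.log10(h),
        gas_c=gas_coeff * x,
        dic=dic,
        co2aq=co2aq,
        hco3=hco3,
        co3=co3,
    )


@dataclass
class CarbonateState:
    """Inorganic-carbon state of the active layer."""

    soil_gas_c: float = 0.0        # g C m-2 in soil air
    dic: float = 0.0               # g C m-2 dissolved
    carbonate_mineral: float = 0.0  # g C m-2 as pedogenic carbonate
    ph: float = 7.0
    pco2: float = 4.0e-4           # atm

    @property
    def ic_tot(self) -> float:
        return self.soil_gas_c + self.dic


def step_inorganic_carbon(
    carb: CarbonateState,
    r_het: float,
    r_aut: float,
    precip_infiltration: float,
    leach_rate: float,
    atm_co2_ppm: float,
    alk: float,
    temp_c: float,
    porosity: float,
    s_eff: float,
    z_a: float,
    dic_rain: float = 0.2,
    w_camgco3: float = 0.0,
    dt: float = 600.0,
) -> tuple[CarbonateState, dict[str, float]]:
    """One 10-minute total-inorganic-carbon sub-step at fixed alkalinity.

    The pool gains respiration (``r_het + r_aut``, g C m-2 per step),
    rain DIC (``precip_infiltration`` m x ``dic_rain`` g C m-3) and any
    carbonate-mineral dissolution ``w_camgco3``; gas and aqueous phases are
    re-equilibrated to the charge-balance pH; losses are the
    Millington-Quirk diffusive efflux against the atmospheric CO2
    concentration and proportional DIC leaching (``leach_rate`` per step).
    """
    if r_het < 0 or r_aut < 0:
        raise ParameterError("respiration inputs must be >= 0")
    v_w = s_eff * porosity * z_a
    v_air = porosity * (1.0 - s_eff) * z_a
    ic = carb.ic_tot + r_het + r_aut + precip_infiltration * dic_rain + w_camgco3
    part = equilibrate_inorganic_carbon(
        ic, alk, temp_c, v_air, max(v_w, 1e-9), pco2_guess=carb.pco2
    )
    t_k = temp_c + 273.15
    c_atm = atm_co2_ppm * 1e-6 * ATM_PA / (R_GAS * t_k) * ATOMIC_MASS["C"]
    k_eff = co2_efflux_coefficient(temp_c, porosity, s_eff, z_a)
    c_soil = part["gas_c"] / max(v_air, 1e-9)
    efflux = k_eff * (c_soil - c_atm) * dt
    if efflux > 0.0:
        efflux = min(efflux, part["gas_c"])
    lk = min(part["dic"] * leach_rate, part["dic"])
    ic -= efflux + lk
    if ic < -1e-9:
        raise ChemistryError(f"inorganic-C pool driven negative: {ic}")
    total_part = part["gas_c"] + part["dic"]
    gas_share = part["gas_c"] / total_part if total_part > 0.0 else 0.0
    new = CarbonateState(
        soil_gas_c=ic * gas_share,
        dic=ic * (1.0 - gas_share),
        carbonate_mineral=carb.carbonate_mineral,
        ph=part["ph"],
        pco2=part["pco2"],
    )
    fluxes = dict(efflux=efflux, dic_leach=lk, rain_dic=precip_infiltration * dic_rain)
    return new, fluxes


def co2_efflux_coefficient(
    temp_c: float, porosity: float, s_eff: float, z_a: float
) -> float:
    """Soil-to-atmosphere CO2 conductance, m s-1 (Millington-Quirk).

    ``D_eff = D0(T) * eps**(10/3) / porosity**2`` over the half-layer
    diffusion length ``z_a / 2``; advection is folded into this single
    effective conductance.
    """
    eps = porosity * (1.0 - s_eff)
    if eps <= 0.0:
        return 0.0
    d0 = D0_CO2 * ((temp_c + 273.15) / 273.15) ** 1.75
    d_eff = d0 * eps ** (10.0 / 3.0) / porosity**2
    return d_eff / (z_a / 2.0)


def carbonate_mineral_step(
    ca_mol_l: float,
    co3_mol_l: float,
    mineral_g_c: float,
    k_p: float,
    dt_s: float,
    temp_c: float = 25.0,
) -> float:
    """Pedogenic carbonate precipitation/dissolution, signed g C m-2.

    ``SI = log10([Ca][CO3]/K_sp)``; W < 0 (precipitation, C uptake) at rate
    ``k_p * (10**SI - 1)`` when SI > 0; W > 0 (dissolution) of existing
    mineral when SI < 0, capped by the available pool.  ``k_p`` is in
    g C m-2 d-1 per unit saturation departure.
    """
    ksp = calcite_ksp(temp_c)
    iap = ca_mol_l * co3_mol_l
    if iap <= 0.0:
        omega = 0.0
    else:
        omega = iap / ksp
    rate_per_s = k_p / 86400.0
    if omega > 1.0:
        return -rate_per_s * (omega - 1.0) * dt_s
    if omega < 1.0 and mineral_g_c > 0.0:
        return min(rate_per_s * (1.0 - omega) * dt_s, mineral_g_c)
    return 0.0


def calcite_saturation_ratio(ca_mol_l: float, co3_mol_l: float, temp_c: float) -> float:
    """Omega = IAP / K_sp for calcite (0 when either ion is absent)."""
    iap = ca_mol_l * co3_mol_l
    return iap / calcite_ksp(temp_c) if iap > 0.0 else 0.0


def coupled_exchange_carbonate(
    solutes: dict[str, float],
    exchanger: "ExchangeComplex",
    ic_tot: float,
    temp_c: float,
    v_air: float,
    v_w: float,
    ph_guess: float = 6.5,
    pco2_guess: float = 4.0e-3,  # kept for signature stability; unused
) -> dict[str, float]:
    """Self-consistent cation-exchange + carbonate-system solve.

    Exchangeable acidity responds to the H+ activity, which itself sets how
    much base-cation charge (alkalinity) stays in solution; lagging the two
    across sub-steps is violently unstable because the exchanger stock
    dwarfs the dissolved stock.  The pair therefore collapses to one scalar
    equation in pH: at a trial pH the exchange equilibrium fixes ALK, the
    open-system charge balance then gives pCO2 in closed form, and the only
    residual is the total inorganic-carbon mass, which is monotone
    (decreasing) in pH.  Solved by bracketed Illinois iteration from a warm
    start.  Mutates ``solutes`` and ``exchanger``; returns the carbonate
    partition (pco2 atm, ph, gas_c / dic g C m-2, mol/L speciation).
    """
    kh, k1, k2, kw = carbonate_constants(temp_c)
    t_k = temp_c + 273.15
    gas_coeff = ATM_PA / (R_GAS * t_k) * ATOMIC_MASS["C"] * v_air  # g C per atm

    if ic_tot <= 0.0:
        exchange_equilibrium(solutes, exchanger, v_w, h_activity=10.0 ** (-ph_guess))
        return dict(pco2=0.0, ph=ph_guess, gas_c=0.0, dic=0.0, co2aq=0.0, hco3=0.0, co3=0.0)

    def evaluate(ph: float) -> tuple[float, dict[str, float]]:
        h = 10.0 ** (-ph)
        exchange_equilibrium(solutes, exchanger, v_w, h_activity=h)
        alk_l = alkalinity(solutes, v_w) / 1000.0
        pco2 = (alk_l - kw / h + h) / (kh * k1 * (1.0 / h + 2.0 * k2 / h**2))
        if pco2 <= 0.0:
            return -ic_tot, dict(pco2=0.0, ph=ph, gas_c=0.0, dic=0.0,
                                 co2aq=0.0, hco3=0.0, co3=0.0)
        co2aq = kh * pco2
        hco3 = k1 * co2aq / h
        co3 = k2 * hco3 / h
        gas = gas_coeff * pco2
        dic = (co2aq + hco3 + co3) * 1000.0 * v_w * ATOMIC_MASS["C"]
        part = dict(pco2=pco2, ph=ph, gas_c=gas, dic=dic,
                    co2aq=co2aq, hco3=hco3, co3=co3)
        return gas + dic - ic_tot, part

    tol = 1e-10 * max(ic_tot, 1.0)
    lo_lim, hi_lim = 1.0, 13.8
    x0 = min(max(ph_guess, lo_lim), hi_lim)
    f0, part = evaluate(x0)
    if abs(f0) < tol and part["pco2"] > 0.0:
        return part

    # expand a bracket around the warm start (residual decreases with pH)
    step = 0.25 if f0 > 0.0 else -0.25
    x1, f1 = x0, f0
    for _ in range(64):
        x_next = min(max(x1 + step, lo_lim), hi_lim)
        f_next, part = evaluate(x_next)
        if f_next == 0.0:
            return part
        if (f_next > 0.0) != (f1 > 0.0):
            lo_x, lo_f = (x1, f1) if f1 > 0.0 else (x_next, f_next)
            hi_x, hi_f = (x_next, f_next) if f_next <= 0.0 else (x1, f1)
            break
        if x_next in (lo_lim, hi_lim):
            return part  # pinned at the physical limit
        x1, f1 = x_next, f_next
        step *= 1.7
    else:
        raise ChemistryError(
            f"coupled chemistry solve found no bracket "
            f"(ic_tot={ic_tot}, T={temp_c}, v_w={v_w})"
        )

    # Illinois regula falsi on [lo_x (f>0), hi_x (f<=0)]
    side = 0
    for _ in range(100):
        x_mid = (lo_f * hi_x - hi_f * lo_x) / (lo_f - hi_f)
        if not (min(lo_x, hi_x) < x_mid < max(lo_x, hi_x)):
            x_mid = 0.5 * (lo_x + hi_x)
        f_mid, part = evaluate(x_mid)
        if abs(f_mid) < tol or abs(hi_x - lo_x) < 1e-11:
            return part
        if f_mid > 0.0:
            lo_x, lo_f = x_mid, f_mid
            if side == 1:
                hi_f *= 0.5
            side = 1
        else:
            hi_x, hi_f = x_mid, f_mid
            if side == -1:
                lo_f *= 0.5
            side = -1
    raise ChemistryError(
        f"coupled chemistry solve did not converge "
        f"(ic_tot={ic_tot}, T={temp_c}, bracket=({lo_x}, {hi_x}))"
    )


@dataclass
class ExchangeComplex:
    """Soil exchange complex: capacity, occupancy, selectivities."""

    cec: float  # mol_c m-2
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(Ca=0.65, Mg=0.15, K=0.04, Na=0.01, acidity=0.15)
    )
    selectivities: dict[str, float] = field(
        default_factory=lambda: dict(Ca=1.0, Mg=1.0, K=0.2, Na=0.05, H=1.0e8)
    )

    def __post_init__(self) -> None:
        if self.cec <= 0:
            raise ParameterError("CEC must be > 0")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"exchange fractions sum to {total}, expected 1")

    def equivalents(self, species: str) -> float:
        return self.fractions.get(species, 0.0) * self.cec


def base_saturation(exchanger: ExchangeComplex) -> float:
    """Percentage of exchange sites occupied by Ca + Mg + K + Na."""
    return 100.0 * sum(exchanger.fractions.get(x, 0.0) for x in BASE_CATIONS)


def exchange_equilibrium(
    solutes: dict[str, float],
    exchanger: ExchangeComplex,
    water_volume: float,
    h_activity: float | None = None,
    tol: float = 1e-13,
    max_iter: int = 200,
) -> tuple[dict[str, float], ExchangeComplex]:
    """Equilibrate solution and exchangeable Ca, Mg, K, Na (in place).

    Total mass per base cation (solution + exchanger) is conserved exactly:
    the equilibrium reduces to a single monotone scalar equation in the
    exchange potential u (occupancy must sum to the CEC), solved by
    bracketed bisection/secant.  If ``h_activity`` (mol/L) is given,
    exchangeable acidity competes as an H+ species whose solution activity
    is externally buffered by the pH solve; otherwise the acidity fraction
    is held fixed and the bases equilibrate over the remaining sites.
    Raises :class:`ChemistryError` with a state dump on non-convergence.
    """
    if water_volume <= 0:
        raise ParameterError("water_volume must be > 0")
    cec = exchanger.cec
    sel = exchanger.selectivities
    k_h = sel.get("H", 0.0) if h_activity is not None else 0.0

    totals = {  # mol m-2
        x: solutes.get(x, 0.0) / ATOMIC_MASS[x] + exchanger.equivalents(x) / CHARGE[x]
        for x in BASE_CATIONS
    }
    if all(t <= 0.0 for t in totals.values()):
        return solutes, exchanger
    target = 1.0 if h_activity is not None else 1.0 - exchanger.fractions.get("acidity", 0.0)

    # per-cation coefficients: q_x(v) = cec*g*T/(1 + cec*g/z), g = s_x*v^z/(1000 Vw)
    inv_vw = 1.0 / (1000.0 * water_volume)
    coef = []
    for x in BASE_CATIONS:
        z = CHARGE[x]
        s = sel[x] * inv_vw if z == 2 else math.sqrt(sel[x]) * inv_vw
        coef.append((x, z, s, totals[x]))
    ah_term = math.sqrt(k_h) * h_activity if k_h > 0.0 else 0.0

    def occ_and_slope(v: float) -> tuple[float, float]:
        occ = ah_term * v
        slope = ah_term
        for _x, z, s, t in coef:
            g = s * (v * v if z == 2 else v)
            denom = 1.0 + cec * g / z
            occ += g * t / denom
            dq_dg = t / (denom * denom)
            slope += dq_dg * (2.0 * g / v if z == 2 else s) if v > 0.0 else (
                dq_dg * (0.0 if z == 2 else s)
            )
        return occ, slope

    # warm-started safeguarded Newton on v = sqrt(u); occ is monotone in v
    v = getattr(exchanger, "_v_warm", 1.0)
    if not (v > 0.0 and math.isfinite(v)):
        v = 1.0
    v_lo, v_hi = 0.0, math.inf
    degenerate = False
    for it in range(max_iter):
        occ, slope = occ_and_slope(v)
        err = occ - target
        if abs(err) < tol:
            break
        if err > 0.0:
            v_hi = v
        else:
            v_lo = v
        if slope > 0.0:
            v_new = v - err / slope
        else:
            v_new = -1.0
        if not (v_lo < v_new < v_hi):
            v_new = 0.5 * (v_lo + v_hi) if math.isfinite(v_hi) else v * 4.0
        if v_new > 1e18:
            degenerate = True  # exchanger cannot be filled: all mass adsorbs
            break
        if abs(v_new - v) <= 1e-15 * max(v, 1e-300):
            v = v_new
            break
        v = v_new
    else:
        raise ChemistryError(
            f"exchange equilibrium did not converge; totals={totals}, "
            f"h_activity={h_activity}, v={v}"
        )
    exchanger._v_warm = v

    if degenerate:
        q = {x: totals[x] * CHARGE[x] for x in BASE_CATIONS}
    else:
        q = {}
        for x, z, s, t in coef:
            g = s * (v * v if z == 2 else v)
            q[x] = cec * g * t / (1.0 + cec * g / z)

    for x in BASE_CATIONS:
        exchanger.fractions[x] = q[x] / cec
        solutes[x] = max(totals[x] - q[x] / CHARGE[x], 0.0) * ATOMIC_MASS[x]
    exchanger.fractions["acidity"] = max(
        0.0, 1.0 - sum(exchanger.fractions[x] for x in BASE_CATIONS)
    )
    return solutes, exchanger
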