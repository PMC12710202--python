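"""Physical constants and thermodynamic reference values.

Equilibrium constants are given at the 25 degC reference temperature and
adjusted with van 't Hoff using the tabulated reaction enthalpies.
All aqueous constants are on a mol/L basis; gas solubility on mol/(L atm).
"""

# Gas constant, J mol-1 K-1
R_GAS = 8.314462618

T_REF_K = 298.15
ATM_PA = 101325.0

# Atomic / molecular masses, g mol-1
ATOMIC_MASS = {
    "Ca": 40.078,
    "Mg": 24.305,
    "K": 39.098,
    "Na": 22.990,
    "Si": 28.085,
    "Al": 26.982,
    "P": 30.974,
    "C": 12.011,
    "N": 14.007,
}
M_CO2 = 44.009

# Cation charges used in alkalinity and exchange calculations
CHARGE = {"Ca": 2, "Mg": 2, "K": 1, "Na": 1, "NH4": 1, "NO3": 1}

# Carbonate system at 25 degC (freshwater, infinite dilution)
LOG10_KH = -1.47      # CO2(g) <-> H2CO3*,  mol L-1 atm-1
LOG10_K1 = -6.35      # H2CO3* <-> H+ + HCO3-
LOG10_K2 = -10.33     # HCO3-  <-> H+ + CO3--
LOG10_KW = -14.0      # water autoionisation
LOG10_KSP_CALCITE = -8.48

# van 't Hoff enthalpies, kJ mol-1 (sign convention: dlnK/dT = dH/(R T^2))
DH_KH = -19.4
DH_K1 = 9.1
DH_K2 = 14.9
DH_KW = 55.8
DH_KSP_CALCITE = -9.6

# Free-air CO2 diffusivity at 0 degC, m2 s-1 (scaled as (T/273.15)^1.75)
D0_CO2 = 1.39e-5

HOURS_PER_DAY = 24
SUBSTEPS_PER_HOUR = 6
SUBSTEP_SECONDS = 600.0
DAYS_PER_YEAR = 365
HOURS_PER_YEAR = DAYS_PER_YEAR * HOURS_PER_DAY


def vant_hoff(log10_k25: float, dh_kj: float, temp_c: float) -> float:
    """Temperature-adjusted equilibrium constant (linear basis)."""
    import math

    t_k = temp_c + 273.15
    ln_k = math.log(10.0) * log10_k25 + (dh_kj * 1000.0 / R_GAS) * (
        1.0 / T_REF_K - 1.0 / t_k
    )
    return math.exp(ln_k)
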