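"""Hourly lumped soil-water balance and soil temperature.

A single bucket of depth ``z_a`` (the biogeochemically active layer)
replaces a multi-layer Richards solver: the layer is vertically lumped for
all chemistry, so a bucket preserves the moisture statistics that drive
weathering.  Drainage is unit-gradient ``K_s * s_eff**c`` with a
Clapp-Hornberger-style exponent ``c = 2b + 3`` from the texture class.
Potential evapotranspiration uses a Priestley-Taylor expression on
shortwave radiation and air temperature, split into transpiration by a
Beer-law canopy fraction and limited by a linear soil-moisture stress
between wilting point and field capacity.  Sub-zero precipitation feeds a
trivial degree-day snow store.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError, StepError


@dataclass
class HydroParams:
    z_a: float            # m
    porosity: float
    field_capacity: float  # volumetric
    wilting_point: float   # volumetric
    k_s: float             # mm h-1
    b_exponent: float
    pt_alpha: float = 1.26
    albedo: float = 0.23
    snow_ddf: float = 0.15  # mm degC-1 h-1
    lw_loss: float = 60.0   # W m-2 net longwave loss when the sun is up
    damping_days: float = 10.0
    soil_temp_floor: bool = False

    @property
    def leak_exponent(self) -> float:
        return 2.0 * self.b_exponent + 3.0

    @property
    def capacity_mm(self) -> float:
        return self.porosity * self.z_a * 1000.0


@dataclass
class SoilHydroState:
    s_eff: float           # effective saturation [0, 1]
    soil_temp: float       # degC
    snow_mm: float = 0.0

    def water_volume(self, params: HydroParams) -> float:
        """Stored water, m3 water per m2 ground."""
        return self.s_eff * params.porosity * params.z_a


@dataclass
class WaterFluxes:
    infiltration: float = 0.0  # mm h-1
    runoff: float = 0.0
    evaporation: float = 0.0
    transpiration: float = 0.0
    leakage: float = 0.0
    snowmelt: float = 0.0
    pet: float = 0.0


def potential_et(
    air_temp: float, sw_down: float, alpha: float, albedo: float, lw_loss: float = 60.0
) -> float:
    """Priestley-Taylor-type potential evapotranspiration, mm h-1.

    Net radiation is approximated as absorbed shortwave minus a constant
    longwave loss while the sun is up.
    """
    es = 0.6108 * math.exp(17.27 * air_temp / (air_temp + 237.3))
    delta = 4098.0 * es / (air_temp + 237.3) ** 2  # kPa degC-1
    gamma = 0.066
    rn = max(0.0, (1.0 - albedo) * sw_down - (lw_loss if sw_down > 0.0 else 0.0))
    lam = 2.45e6  # J kg-1
    return max(0.0, alpha * delta / (delta + gamma) * rn / lam * 3600.0)


def step_soil_water(
    state: SoilHydroState,
    air_temp: float,
    precip: float,
    sw_down: float,
    lai: float,
    params: HydroParams,
) -> tuple[SoilHydroState, WaterFluxes]:
    """Advance the bucket one hour; the water balance closes exactly.

    ``delta_storage = infiltration - evaporation - transpiration - leakage``
    with ``infiltration = rain + snowmelt - runoff`` and runoff generated
    only by saturation excess.
    """
    if not (math.isfinite(air_temp) and math.isfinite(precip) and math.isfinite(sw_down)):
        raise StepError(
            f"NaN/inf forcing in hour step (air_temp={air_temp}, "
            f"precip={precip}, sw_down={sw_down})"
        )
    if lai < 0:
        raise ParameterError("lai must be >= 0")

    fl = WaterFluxes()
    snow = state.snow_mm
    if air_temp <= 0.0:
        snow += precip
        rain = 0.0
    else:
        rain = precip
        melt = min(snow, params.snow_ddf * air_temp)
        snow -= melt
        fl.snowmelt = melt

    storage = state.s_eff * params.capacity_mm
    supply = rain + fl.snowmelt
    room = params.capacity_mm - storage
    fl.infiltration = min(supply, room)
    fl.runoff = supply - fl.infiltration
    storage += fl.infiltration

    fl.pet = potential_et(air_temp, sw_down, params.pt_alpha, params.albedo, params.lw_loss)
    transp_frac = 1.0 - math.exp(-0.5 * lai)
    theta = storage / (params.z_a * 1000.0)  # volumetric
    beta = (theta - params.wilting_point) / (params.field_capacity - params.wilting_point)
    beta = min(1.0, max(0.0, beta))
    et_pot = fl.pet * beta
    transp = et_pot * transp_frac
    evap = et_pot - transp
    avail = max(0.0, storage - params.wilting_point * params.z_a * 1000.0)
    total_et = transp + evap
    if total_et > avail and total_et > 0.0:
        scale = avail / total_et
        transp *= scale
        evap *= scale
    fl.transpiration = transp
    fl.evaporation = evap
    storage -= transp + evap

    s_now = storage / params.capacity_mm
    leak = params.k_s * s_now ** params.leak_exponent
    fl.leakage = min(leak, storage)
    storage -= fl.leakage

    new = SoilHydroState(
        s_eff=min(1.0, max(0.0, storage / params.capacity_mm)),
        soil_temp=update_soil_temperature(
            state.soil_temp, air_temp, params.damping_days, params.soil_temp_floor
        ),
        snow_mm=snow,
    )
    return new, fl


def update_soil_temperature(
    soil_temp: float, air_temp: float, damping_days: float, floor: bool = False
) -> float:
    """One hourly update of the exponential soil-temperature filter."""
    if damping_days <= 0:
        raise ParameterError("damping_days must be > 0")
    alpha = 1.0 - math.exp(-(1.0 / 24.0) / damping_days)
    t = soil_temp + alpha * (air_temp - soil_temp)
    return max(0.0, t) if floor else t


def soil_temperature(air_temp_series, damping_days: float, floor: bool = False):
    """Exponential moving average of an hourly air-temperature series.

    The e-folding time is ``damping_days``; after a step change the filter
    output reaches ``1 - 1/e`` of the step after exactly ``damping_days``.
    """
    if damping_days <= 0:
        raise ParameterError("damping_days must be > 0")
    out = []
    t = float(air_temp_series[0])
    for ta in air_temp_series:
        t = update_soil_temperature(t, float(ta), damping_days, floor)
        out.append(t)
    return out
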