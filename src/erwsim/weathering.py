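"""Kinetic dissolution of the applied mineral assemblage.

The rate law is the multi-mechanism Palandri-Kharaka form with two
modifications: a linear soil-moisture factor ``s_eff`` (dissolution acts
on water-exposed mineral surfaces) and a dimensionless dissolution factor
``F_D`` absorbing uncharacterised biotic/abiotic field effects.  A
``(1 - min(omega, 1))`` factor shuts dissolution off at saturation; omega
is computed only for carbonates (silicates default to far-from-equilibrium
omega = 0).  Reactive surface area per application cohort follows the
shrinking-particle rule ``A = A0 * (m / m0)**(2/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import FeedstockEvent
from .constants import ATOMIC_MASS
from .errors import ConfigError, ParameterError
from .minerals import MineralKinetics

RELEASE_ELEMENTS = ("Ca", "Mg", "K", "Na", "Si", "Al", "P", "C")


def dissolution_rate(
    mineral: MineralKinetics,
    ph: float,
    soil_temp: float,
    s_eff: float,
    omega: float = 0.0,
    f_d: float = 1.0,
) -> float:
    """Area-specific dissolution rate, mol m-2 s-1.

    ``rate = F_D * s_eff * (1 - min(omega, 1)) *
    sum_m k_m(25C) * exp[-Ea_m/R (1/T - 1/298.15)] * (10**-pH)**n_m``
    """
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH outside [0, 14]: {ph}")
    if not 0.0 <= s_eff <= 1.0:
        raise ParameterError(f"s_eff outside [0, 1]: {s_eff}")
    if omega < 0:
        raise ParameterError(f"omega must be >= 0: {omega}")
    if f_d < 0:
        raise ParameterError(f"F_D must be >= 0: {f_d}")
    sat = 1.0 - min(omega, 1.0)
    if f_d == 0.0 or s_eff == 0.0 or sat == 0.0:
        return 0.0
    return f_d * s_eff * sat * mineral.rate_constant(soil_temp, 10.0 ** (-ph))


@dataclass
class Cohort:
    """One application event's per-mineral mass and initial geometry."""

    mineral: str
    mass: float        # kg m-2 remaining
    mass0: float       # kg m-2 applied
    area0: float       # m2 m-2 at application

    @property
    def area(self) -> float:
        if self.mass <= 0.0 or self.mass0 <= 0.0:
            return 0.0
        return self.area0 * (self.mass / self.mass0) ** (2.0 / 3.0)


@dataclass
class FeedstockState:
    """Remaining feedstock and cumulative dissolved element inventory."""

    cohorts: list[Cohort] = field(default_factory=list)
    dissolved_moles: dict[str, float] = field(
        default_factory=lambda: {el: 0.0 for el in RELEASE_ELEMENTS}
    )

    def mass_of(self, mineral: str) -> float:
        return sum((c.mass for c in self.cohorts if c.mineral == mineral), 0.0)

    def area_of(self, mineral: str) -> float:
        return sum((c.area for c in self.cohorts if c.mineral == mineral), 0.0)

    @property
    def total_mass(self) -> float:
        return sum((c.mass for c in self.cohorts), 0.0)

    def stoichiometric_content(self, library: dict[str, MineralKinetics]) -> dict[str, float]:
        """Total element content (g m-2) of remaining + dissolved feedstock."""
        content = {el: 0.0 for el in RELEASE_ELEMENTS}
        for c in self.cohorts:
            mineral = library[c.mineral]
            moles = c.mass0 * 1000.0 / mineral.molar_mass
            for el, nu in mineral.stoichiometry.items():
                content[el] += moles * nu * ATOMIC_MASS[el]
        return content


def apply_feedstock_event(
    state: FeedstockState,
    event: FeedstockEvent,
    library: dict[str, MineralKinetics],
) -> FeedstockState:
    """Add one application's mineral cohorts to the feedstock state."""
    unknown = [m for m in event.mineral_fractions if m not in library]
    if unknown:
        raise ConfigError(
            f"feedstock references minerals absent from the kinetics library: {unknown}"
        )
    for mineral, frac in event.mineral_fractions.items():
        mass = event.rate * frac
        if mass <= 0.0:
            continue
        state.cohorts.append(
            Cohort(
                mineral=mineral,
                mass=mass,
                mass0=mass,
                area0=mass * event.specific_surface_area,
            )
        )
    return state


def step_feedstock(
    state: FeedstockState,
    library: dict[str, MineralKinetics],
    ph: float,
    soil_temp: float,
    s_eff: float,
    omega: dict[str, float] | None,
    f_d: float,
    dt: float = 600.0,
) -> dict[str, float]:
    """Dissolve each cohort for ``dt`` seconds; returns element release, g m-2.

    Dissolved moles per cohort are ``rate * area * dt`` capped at the
    remaining moles; the returned mapping covers Ca, Mg, K, Na, Si, Al, P
    and carbonate C.  The state is updated in place.
    """
    if dt < 0:
        raise ParameterError(f"dt must be >= 0, got {dt}")
    release = {el: 0.0 for el in RELEASE_ELEMENTS}
    if not state.cohorts:
        return release
    rate_cache: dict[str, float] = {}
    for cohort in state.cohorts:
        if cohort.mass <= 0.0:
            continue
        mineral = library[cohort.mineral]
        rate = rate_cache.get(cohort.mineral)
        if rate is None:
            om = omega.get(cohort.mineral, 0.0) if omega else 0.0
            rate = dissolution_rate(mineral, ph, soil_temp, s_eff, om, f_d)
            rate_cache[cohort.mineral] = rate
        if rate == 0.0:
            continue
        moles = rate * cohort.area * dt
        remaining = cohort.mass * 1000.0 / mineral.molar_mass
        if moles >= remaining:
            moles = remaining
            cohort.mass = 0.0
        else:
            cohort.mass -= moles * mineral.molar_mass / 1000.0
        for el, nu in mineral.stoichiometry.items():
            grams = moles * nu * ATOMIC_MASS[el]
            release[el] += grams
            state.dissolved_moles[el] += moles * nu
    return release
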