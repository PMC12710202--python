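import math

import numpy as np
import pytest

from erwsim.config import FeedstockEvent
from erwsim.constants import ATOMIC_MASS, R_GAS
from erwsim.errors import ConfigError, ParameterError
from erwsim.minerals import Mechanism, MineralKinetics
from erwsim.weathering import (
    FeedstockState,
    apply_feedstock_event,
    dissolution_rate,
    step_feedstock,
)
import pandas as pd


def neutral_only_olivine() -> MineralKinetics:
    """Forsterite-like mineral with a single neutral mechanism."""
    return MineralKinetics(
        name="olivine_test", molar_mass=140.69,
        stoichiometry={"Mg": 2.0, "Si": 1.0},
        mechanisms=[Mechanism("neutral", -10.64, 79.0, 0.0)],
    )


def acid_only_mineral() -> MineralKinetics:
    return MineralKinetics(
        name="acid_test", molar_mass=100.0, stoichiometry={"Ca": 1.0},
        mechanisms=[Mechanism("acid", -8.0, 50.0, 0.5)],
    )


class TestDissolutionRate:
    def test_neutral_rate_at_reference_conditions(self):
        # hand evaluation: rate = 10**-10.64 at 25 C, s_eff 1, omega 0, F_D 1
        rate = dissolution_rate(neutral_only_olivine(), 7.0, 25.0, 1.0, 0.0, 1.0)
        assert rate == pytest.approx(10.0 ** -10.64, rel=1e-12)
        assert rate == pytest.approx(2.29e-11, rel=0.01)

    @pytest.mark.parametrize("kwargs,expected_zero", [
        (dict(f_d=0.0), True),
        (dict(s_eff=0.0), True),
        (dict(omega=1.0), True),
        (dict(omega=2.5), True),
    ])
    def test_multiplicative_zeroes(self, kwargs, expected_zero):
        base = dict(ph=6.0, soil_temp=18.0, s_eff=0.7, omega=0.0, f_d=1.0)
        base.update(kwargs)
        rate = dissolution_rate(neutral_only_olivine(), base["ph"], base["soil_temp"],
                                base["s_eff"], base["omega"], base["f_d"])
        assert (rate == 0.0) is expected_zero

    def test_f_d_linearity_exact(self):
        m = acid_only_mineral()
        r1 = dissolution_rate(m, 5.5, 20.0, 0.6, 0.0, 1.0)
        r2 = dissolution_rate(m, 5.5, 20.0, 0.6, 0.0, 2.0)
        rhalf = dissolution_rate(m, 5.5, 20.0, 0.6, 0.0, 0.5)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-15)
        assert rhalf == pytest.approx(0.5 * r1, rel=1e-15)

    def test_arrhenius_ratio_exact(self):
        m = neutral_only_olivine()
        r25 = dissolution_rate(m, 7.0, 25.0, 1.0, 0.0, 1.0)
        r35 = dissolution_rate(m, 7.0, 35.0, 1.0, 0.0, 1.0)
        expected = math.exp(-(79.0e3 / R_GAS) * (1.0 / 308.15 - 1.0 / 298.15))
        assert r35 / r25 == pytest.approx(expected, rel=1e-12)

    def test_acid_mechanism_rate_monotone_nonincreasing_in_ph(self):
        m = acid_only_mineral()
        rates = [dissolution_rate(m, ph, 20.0, 1.0, 0.0, 1.0)
                 for ph in np.linspace(3.0, 10.0, 30)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_preconditions(self):
        m = neutral_only_olivine()
        with pytest.raises(ParameterError):
            dissolution_rate(m, -1.0, 20.0, 0.5)
        with pytest.raises(ParameterError):
            dissolution_rate(m, 7.0, 20.0, 1.5)
        with pytest.raises(ParameterError):
            dissolution_rate(m, 7.0, 20.0, 0.5, omega=-0.1)


class TestFeedstockStepping:
    def make_event(self, fractions, rate=5.0, ssa=1000.0):
        return FeedstockEvent(
            date=pd.Timestamp("2017-06-01"), rate=rate,
            mineral_fractions=fractions, specific_surface_area=ssa,
        )

    def test_apply_event_masses(self, mineral_library):
        state = FeedstockState()
        fr = {"albite": 0.196, "ferroactinolite": 0.116, "epidote": 0.256,
              "chlorite": 0.363, "quartz": 0.052}
        apply_feedstock_event(state, self.make_event(fr), mineral_library)
        assert state.mass_of("albite") == pytest.approx(0.98, abs=1e-12)
        assert state.mass_of("chlorite") == pytest.approx(1.815, abs=1e-12)

    def test_zero_rate_is_noop(self, mineral_library):
        state = FeedstockState()
        apply_feedstock_event(state, self.make_event({"albite": 1.0}, rate=0.0),
                              mineral_library)
        assert state.total_mass == 0.0

    def test_two_identical_events_double_masses(self, mineral_library):
        state = FeedstockState()
        ev = self.make_event({"albite": 0.5, "quartz": 0.5})
        apply_feedstock_event(state, ev, mineral_library)
        apply_feedstock_event(state, ev, mineral_library)
        assert state.mass_of("albite") == pytest.approx(5.0)

    def test_unknown_mineral_rejected(self, mineral_library):
        state = FeedstockState()
        with pytest.raises(ConfigError, match="kryptonite"):
            apply_feedstock_event(state, self.make_event({"kryptonite": 1.0}),
                                  mineral_library)

    def test_empty_feedstock_releases_nothing(self, mineral_library):
        state = FeedstockState()
        rel = step_feedstock(state, mineral_library, 6.0, 20.0, 0.6, None, 1.0)
        assert all(v == 0.0 for v in rel.values())

    def test_capping_releases_exact_stoichiometric_content(self):
        lib = {"olivine_test": neutral_only_olivine()}
        state = FeedstockState()
        ev = FeedstockEvent(pd.Timestamp("2017-06-01"), 0.001,
                            {"olivine_test": 1.0}, 1e9)  # absurd area: demand >> stock
        apply_feedstock_event(state, ev, lib)
        moles0 = 0.001 * 1000.0 / 140.69
        rel = step_feedstock(state, lib, 7.0, 25.0, 1.0, None, 1.0)
        assert state.mass_of("olivine_test") == 0.0
        assert rel["Mg"] == pytest.approx(moles0 * 2 * ATOMIC_MASS["Mg"], rel=1e-12)
        assert rel["Si"] == pytest.approx(moles0 * ATOMIC_MASS["Si"], rel=1e-12)

    def test_two_mineral_release_equals_sum_of_singles(self, mineral_library):
        # oracle: evaluate each mineral independently and sum
        def run(fractions):
            st = FeedstockState()
            apply_feedstock_event(st, self.make_event(fractions), mineral_library)
            return step_feedstock(st, mineral_library, 5.5, 22.0, 0.8, None, 1.0)

        combo = run({"epidote": 0.5, "ferroactinolite": 0.5})
        a = run({"epidote": 0.5})
        b = run({"ferroactinolite": 0.5})
        assert combo["Ca"] == pytest.approx(a["Ca"] + b["Ca"], rel=1e-12)
        assert combo["Si"] == pytest.approx(a["Si"] + b["Si"], rel=1e-12)

    def test_cumulative_release_bounded_by_stoichiometric_content(self, mineral_library):
        state = FeedstockState()
        apply_feedstock_event(
            state, self.make_event({"albite": 0.6, "quartz": 0.4}, ssa=1e7),
            mineral_library,
        )
        content = state.stoichiometric_content(mineral_library)
        total = {el: 0.0 for el in content}
        for _ in range(500):
            rel = step_feedstock(state, mineral_library, 4.0, 30.0, 1.0, None, 10.0)
            for el in total:
                total[el] += rel[el]
        for el, released in total.items():
            assert released <= content[el] * (1 + 1e-9)

    def test_negative_dt_rejected(self, mineral_library):
        with pytest.raises(ParameterError):
            step_feedstock(FeedstockState(), mineral_library, 6.0, 20.0, 0.5,
                           None, 1.0, dt=-1.0)

    def test_shrinking_particle_area(self, mineral_library):
        state = FeedstockState()
        apply_feedstock_event(state, self.make_event({"forsterite": 1.0}),
                              mineral_library)
        cohort = state.cohorts[0]
        a0 = cohort.area
        cohort.mass = cohort.mass0 / 8.0
        assert cohort.area == pytest.approx(a0 / 4.0, rel=1e-12)  # (1/8)^(2/3)
        cohort.mass = 0.0
        assert cohort.area == 0.0
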