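import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erwsim.chemistry import (
    BASE_CATIONS,
    CarbonateState,
    ExchangeComplex,
    alkalinity,
    base_saturation,
    calcite_ksp,
    carbonate_constants,
    carbonate_mineral_step,
    coupled_exchange_carbonate,
    dic_speciation_fractions,
    equilibrate_inorganic_carbon,
    exchange_equilibrium,
    solve_carbonate_system,
    step_inorganic_carbon,
)
from erwsim.constants import ATOMIC_MASS, CHARGE
from erwsim.errors import ChemistryError, ParameterError


def masses_from_conc(conc_molm3: dict, water_volume: float) -> dict:
    """Solute masses (g m-2; An_r in mol_c m-2) from mol m-3 concentrations."""
    out = {}
    for key, c in conc_molm3.items():
        if key == "An_r":
            out[key] = c * water_volume
        else:
            el = "N" if key in ("NH4", "NO3") else ("P" if key == "TPO4" else key)
            out[key] = c * water_volume * ATOMIC_MASS[el]
    return out


class TestAlkalinity:
    def test_zero_solutes(self):
        assert alkalinity({}, 0.1) == 0.0

    def test_calcium_charge_factor(self):
        sol = masses_from_conc({"Ca": 0.5}, 1.0)
        assert alkalinity(sol, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_full_charge_balance_hand_value(self):
        conc = dict(Ca=0.5, Mg=0.25, K=0.1, Na=0.2, NH4=0.05,
                    NO3=0.3, An_r=0.1, TPO4=0.05)
        sol = masses_from_conc(conc, 1.0)
        # 2*0.5 + 2*0.25 + 0.1 + 0.2 + 0.05 - 0.3 - 0.1 - 0.05 = 1.40
        assert alkalinity(sol, 1.0) == pytest.approx(1.40, rel=1e-12)

    def test_negative_alkalinity_is_valid(self):
        sol = masses_from_conc({"NO3": 1.0}, 1.0)
        assert alkalinity(sol, 1.0) < 0.0

    def test_zero_water_volume_rejected(self):
        with pytest.raises(ParameterError):
            alkalinity({}, 0.0)


def brute_force_ph(alk_molm3, pco2, temp_c, coarse=1e-3, fine=1e-6):
    """Independent charge-balance scan: coarse grid + local refinement."""
    kh, k1, k2, kw = carbonate_constants(temp_c)
    alk_l = alk_molm3 / 1000.0

    def residual(ph):
        h = 10.0 ** (-ph)
        co2aq = kh * pco2
        hco3 = k1 * co2aq / h
        co3 = k2 * hco3 / h
        return hco3 + 2 * co3 + kw / h - h - alk_l

    grid = np.arange(2.0, 12.0, coarse)
    res = np.array([residual(p) for p in grid])
    i = int(np.argmin(np.abs(res)))
    lo = max(grid[i] - coarse, 2.0)
    fine_grid = np.arange(lo, lo + 2 * coarse, fine)
    fres = np.array([residual(p) for p in fine_grid])
    return float(fine_grid[int(np.argmin(np.abs(fres)))])


class TestCarbonateSystem:
    def test_reference_ph_561(self):
        ph, *_ = solve_carbonate_system(0.0, 3.95e-4, 25.0)
        assert ph == pytest.approx(5.61, abs=0.01)

    def test_pure_water_limit(self):
        ph, *_ = solve_carbonate_system(0.0, 1e-12, 25.0)
        assert ph == pytest.approx(7.00, abs=0.01)

    def test_agreement_with_brute_force_scan(self):
        ph, *_ = solve_carbonate_system(1.0, 1e-2, 25.0)
        assert abs(ph - brute_force_ph(1.0, 1e-2, 25.0)) < 1e-4

    def test_charge_balance_residual_below_1e10(self):
        for alk in (-0.5, 0.0, 2.0, 8.0):
            for pco2 in (4e-4, 5e-3, 5e-2):
                ph, co2aq, hco3, co3 = solve_carbonate_system(alk, pco2, 18.0)
                h = 10.0 ** (-ph) * 1000.0
                _, _, _, kw = carbonate_constants(18.0)
                oh = kw / (10.0 ** (-ph)) * 1000.0
                residual = hco3 + 2 * co3 + oh - h - alk
                assert abs(residual) < 1e-10

    def test_ph_monotone_in_alk_and_pco2(self):
        alks = np.linspace(-1.0, 10.0, 12)
        phs = [solve_carbonate_system(a, 2e-3, 25.0)[0] for a in alks]
        assert all(a < b for a, b in zip(phs, phs[1:]))
        pco2s = np.logspace(-4, -1.5, 10)
        phs = [solve_carbonate_system(1.0, p, 25.0)[0] for p in pco2s]
        assert all(a > b for a, b in zip(phs, phs[1:]))

    def test_speciation_fractions_sum_to_one(self):
        for ph in (3.0, 5.5, 7.0, 9.2, 11.0):
            for t in (2.0, 25.0, 35.0):
                assert sum(dic_speciation_fractions(ph, t)) == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_pco2_rejected(self):
        with pytest.raises(ParameterError):
            solve_carbonate_system(0.0, 0.0, 25.0)

    def test_partition_recovers_total_mass(self):
        part = equilibrate_inorganic_carbon(12.0, 2.0, 15.0, 0.06, 0.07)
        assert part["gas_c"] + part["dic"] == pytest.approx(12.0, rel=1e-9)


class TestCarbonateMineral:
    def test_equilibrium_gives_zero(self):
        ksp = calcite_ksp(25.0)
        ca = math.sqrt(ksp)
        assert abs(carbonate_mineral_step(ca, ca, 5.0, 0.5, 600.0, 25.0)) < 1e-15

    def test_nothing_to_dissolve(self):
        assert carbonate_mineral_step(1e-9, 1e-9, 0.0, 0.5, 600.0, 25.0) == 0.0

    def test_precipitation_rate_hand_value(self):
        ksp = calcite_ksp(25.0)
        si = 0.5
        ca = math.sqrt(ksp * 10.0 ** si)
        w = carbonate_mineral_step(ca, ca, 0.0, 0.5, 600.0, 25.0)
        expected = -0.5 / 86400.0 * (10.0 ** si - 1.0) * 600.0
        assert w == pytest.approx(expected, rel=1e-9)

    def test_dissolution_capped_by_pool(self):
        w = carbonate_mineral_step(0.0, 0.0, 1e-9, 1000.0, 600.0, 25.0)
        assert w == pytest.approx(1e-9)


def make_exchanger(fractions, cec=10.0, k_na=0.05):
    return ExchangeComplex(
        cec=cec, fractions=fractions,
        selectivities=dict(Ca=1.0, Mg=1.0, K=0.2, Na=k_na, H=1e8),
    )


class TestExchange:
    def test_symmetric_monovalent_pair(self):
        ex = ExchangeComplex(
            cec=5.0, fractions=dict(Ca=0.0, Mg=0.0, K=0.5, Na=0.5, acidity=0.0),
            selectivities=dict(Ca=1.0, Mg=1.0, K=1.0, Na=1.0, H=0.0),
        )
        sol = {"K": 2.0 * ATOMIC_MASS["K"], "Na": 2.0 * ATOMIC_MASS["Na"]}
        exchange_equilibrium(sol, ex, 0.1)
        assert ex.fractions["K"] == pytest.approx(0.5, abs=1e-9)
        assert ex.fractions["Na"] == pytest.approx(0.5, abs=1e-9)

    def test_single_cation_fills_exchanger(self):
        ex = make_exchanger(dict(Ca=0.2, Mg=0.0, K=0.0, Na=0.0, acidity=0.8), cec=2.0)
        ex.fractions["acidity"] = 0.0
        ex.fractions["Ca"] = 1.0
        sol = {"Ca": 100.0 * ATOMIC_MASS["Ca"]}  # plenty in solution
        exchange_equilibrium(sol, ex, 0.1)
        assert ex.fractions["Ca"] == pytest.approx(1.0, abs=1e-9)
        # solution holds the remainder of the total mass
        total = 100.0 + 1.0  # mol
        assert sol["Ca"] / ATOMIC_MASS["Ca"] == pytest.approx(total - 1.0, rel=1e-9)

    def test_binary_ca_na_matches_grid_oracle(self):
        cec, vw, k_na = 3.0, 0.08, 0.05
        t_ca, t_na = 2.0, 1.5  # mol m-2 totals
        ex = ExchangeComplex(
            cec=cec, fractions=dict(Ca=0.5, Mg=0.0, K=0.0, Na=0.5, acidity=0.0),
            selectivities=dict(Ca=1.0, Mg=1.0, K=0.2, Na=k_na, H=0.0),
        )
        sol = {
            "Ca": (t_ca - 0.5 * cec / 2) * ATOMIC_MASS["Ca"],
            "Na": (t_na - 0.5 * cec) * ATOMIC_MASS["Na"],
        }
        exchange_equilibrium(sol, ex, vw)

        # independent brute force on the equivalent-fraction grid
        best, best_res = None, math.inf
        for e_ca in np.arange(1e-4, 1.0, 1e-4):
            q_ca, q_na = e_ca * cec, (1 - e_ca) * cec
            c_ca = (t_ca - q_ca / 2) / vw / 1000.0
            c_na = (t_na - q_na) / vw / 1000.0
            if c_ca <= 0 or c_na <= 0:
                continue
            u = e_ca / c_ca
            res = abs((1 - e_ca) - math.sqrt(k_na * u) * c_na)
            if res < best_res:
                best, best_res = e_ca, res
        assert ex.fractions["Ca"] == pytest.approx(best, abs=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        sol_mol=st.tuples(*[st.floats(0.0, 5.0) for _ in range(4)]),
        fr=st.tuples(*[st.floats(0.01, 0.3) for _ in range(4)]),
        ph=st.floats(4.0, 9.0),
    )
    def test_mass_conservation_to_machine_precision(self, sol_mol, fr, ph):
        acidity = 1.0 - sum(fr)
        ex = make_exchanger(
            dict(zip(["Ca", "Mg", "K", "Na"], fr), acidity=acidity), cec=20.0
        )
        sol = {
            x: m * ATOMIC_MASS[x] for x, m in zip(["Ca", "Mg", "K", "Na"], sol_mol)
        }
        before = {
            x: sol[x] / ATOMIC_MASS[x] + ex.equivalents(x) / CHARGE[x]
            for x in BASE_CATIONS
        }
        exchange_equilibrium(sol, ex, 0.07, h_activity=10.0 ** (-ph))
        for x in BASE_CATIONS:
            after = sol[x] / ATOMIC_MASS[x] + ex.equivalents(x) / CHARGE[x]
            assert after == pytest.approx(before[x], rel=1e-12, abs=1e-12)
        assert sum(ex.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestBaseSaturation:
    def test_sum_of_base_fractions(self):
        ex = make_exchanger(dict(Ca=0.5, Mg=0.2, K=0.05, Na=0.05, acidity=0.2))
        assert base_saturation(ex) == pytest.approx(80.0)

    def test_all_acidity(self):
        ex = make_exchanger(dict(Ca=0.0, Mg=0.0, K=0.0, Na=0.0, acidity=1.0))
        assert base_saturation(ex) == 0.0

    def test_consistent_with_binary_equilibrium(self):
        ex = ExchangeComplex(
            cec=3.0, fractions=dict(Ca=0.5, Mg=0.0, K=0.0, Na=0.5, acidity=0.0),
            selectivities=dict(Ca=1.0, Mg=1.0, K=0.2, Na=0.05, H=0.0),
        )
        sol = {"Ca": 30.0, "Na": 20.0}
        exchange_equilibrium(sol, ex, 0.08)
        assert base_saturation(ex) == pytest.approx(
            100.0 * (ex.fractions["Ca"] + ex.fractions["Na"]), rel=1e-12
        )


class TestInorganicCarbonStep:
    GEO = dict(porosity=0.45, s_eff=0.5, z_a=0.3)

    def equilibrated_state(self, pco2, alk=0.0, temp=15.0):
        v_w = self.GEO["s_eff"] * self.GEO["porosity"] * self.GEO["z_a"]
        v_air = self.GEO["porosity"] * (1 - self.GEO["s_eff"]) * self.GEO["z_a"]
        from erwsim.constants import ATM_PA, R_GAS
        gas = pco2 * ATM_PA / (R_GAS * (temp + 273.15)) * ATOMIC_MASS["C"] * v_air
        ph, co2aq, hco3, co3 = solve_carbonate_system(alk, pco2, temp)
        dic = (co2aq + hco3 + co3) * v_w * ATOMIC_MASS["C"]
        return CarbonateState(soil_gas_c=gas, dic=dic, ph=ph, pco2=pco2)

    def test_zero_gradient_steady_state(self):
        carb = self.equilibrated_state(400e-6)
        new, fx = step_inorganic_carbon(
            carb, 0.0, 0.0, 0.0, 0.0, 400.0, 0.0, 15.0, **self.GEO
        )
        assert abs(fx["efflux"]) < 1e-12
        assert new.dic == pytest.approx(carb.dic, rel=1e-6)

    def test_respiration_pulse_conserves_carbon(self):
        carb = self.equilibrated_state(400e-6)
        ic0 = carb.ic_tot
        total_resp, total_efflux = 0.0, 0.0
        for i in range(500):
            r = 0.02 if i < 50 else 0.0
            carb, fx = step_inorganic_carbon(
                carb, r, 0.0, 0.0, 0.0, 400.0, 0.0, 15.0, **self.GEO
            )
            total_resp += r
            total_efflux += fx["efflux"]
        assert (carb.ic_tot - ic0 + total_efflux) == pytest.approx(
            total_resp, rel=1e-8
        )

    def test_leached_reservoir_approaches_fixed_point(self):
        carb = self.equilibrated_state(400e-6)
        source, leach = 0.01, 2e-4
        history = []
        for _ in range(4000):
            carb, fx = step_inorganic_carbon(
                carb, source, 0.0, 0.0, leach, 400.0, 0.0, 15.0, **self.GEO
            )
            history.append(carb.ic_tot)
        # linear reservoir: inflow balances outflow at the fixed point
        assert abs(history[-1] - history[-10]) / history[-1] < 1e-4
        out = fx["efflux"] + fx["dic_leach"]
        assert out == pytest.approx(source, rel=1e-2)

    def test_negative_respiration_rejected(self):
        with pytest.raises(ParameterError):
            step_inorganic_carbon(
                CarbonateState(), -1.0, 0.0, 0.0, 0.0, 400.0, 0.0, 15.0, **self.GEO
            )


class TestCoupledSolve:
    def test_matches_uncoupled_when_exchange_inert(self):
        # with an empty exchanger-interaction (no H competition, tiny CEC)
        ex = ExchangeComplex(
            cec=1e-6, fractions=dict(Ca=0.25, Mg=0.25, K=0.25, Na=0.25, acidity=0.0),
            selectivities=dict(Ca=1.0, Mg=1.0, K=1.0, Na=1.0, H=0.0),
        )
        sol = masses_from_conc(dict(Ca=1.0, Na=0.5), 0.07)
        alk = alkalinity(sol, 0.07)
        part = coupled_exchange_carbonate(dict(sol), ex, 8.0, 15.0, 0.07, 0.07)
        ref = equilibrate_inorganic_carbon(8.0, alk, 15.0, 0.07, 0.07)
        assert part["ph"] == pytest.approx(ref["ph"], abs=1e-5)
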