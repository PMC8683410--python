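"""Thermodynamic chain, ITC integration, heat-capacity fit and the
stochastic reversible-polymerisation check."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilkit import synthgen, thermo
from fibrilkit.errors import InvalidParameterError, NotDeterminedError


class TestIntegrateThermogram:
    def _make(self, baseline, pulses, grid=None):
        return synthgen.gen_thermogram(synthgen.SimSpec(
            "thermogram",
            {"baseline": baseline, "pulses": pulses, "n_mol": 2e-7},
            grid if grid is not None else np.arange(0.0, 600.0, 0.1)))

    def test_flat_zero_trace_integrates_to_zero(self):
        tg = thermo.Thermogram(np.arange(0.0, 100.0, 1.0), np.zeros(100),
                               injections=[(10.0, 1e-7)])
        assert thermo.integrate_thermogram(tg) == [0.0]

    def test_rectangle_on_zero_baseline(self):
        syn = self._make(0.0, [(100.0, 120.0, -5.0)])
        heats = thermo.integrate_thermogram(syn.thermogram)
        assert sum(heats) == pytest.approx(-2.5104e-3, rel=5e-3)

    def test_constant_baseline_is_subtracted_exactly(self):
        syn0 = self._make(0.0, [(100.0, 120.0, -5.0)])
        syn2 = self._make(2.0, [(100.0, 120.0, -5.0)])
        q0 = sum(thermo.integrate_thermogram(syn0.thermogram))
        q2 = sum(thermo.integrate_thermogram(syn2.thermogram))
        assert q2 == pytest.approx(q0, rel=1e-9)

    def test_constant_baseline_needs_preinjection_samples(self):
        tg = thermo.Thermogram(np.arange(0.0, 50.0, 1.0), np.ones(50),
                               injections=[(0.0, 1e-7)])
        with pytest.raises(NotDeterminedError):
            thermo.integrate_thermogram(tg)

    def test_empty_injection_window_warns_and_zeroes(self):
        tg = thermo.Thermogram(np.arange(0.0, 50.0, 1.0), np.zeros(50),
                               injections=[(10.0, 1e-7), (49.5, 1e-7)])
        with pytest.warns(UserWarning):
            heats = thermo.integrate_thermogram(tg)
        assert heats[1] == 0.0

    def test_als_baseline_recovers_pulse_heat(self):
        syn = self._make(3.0, [(200.0, 60.0, -20.0)])
        tg = syn.thermogram
        tg.baseline_model = "als"
        q = sum(thermo.integrate_thermogram(tg))
        assert q == pytest.approx(-20.0 * 60.0 * 1e-6 * 4.184, rel=0.05)


class TestEnthalpy:
    def test_printed_molar_enthalpy_construction(self):
        assert thermo.enthalpy_from_heats(-59.548e-3, 2e-7) \
            == pytest.approx(-297.74, rel=1e-12)

    def test_zero_heat_zero_enthalpy(self):
        assert thermo.enthalpy_from_heats(0.0, 1e-6) == 0.0

    def test_direct_division(self):
        assert thermo.enthalpy_from_heats(-4.184e-3, 1e-6) \
            == pytest.approx(-4.184, rel=1e-12)

    def test_nonpositive_amount_rejected(self):
        with pytest.raises(InvalidParameterError):
            thermo.enthalpy_from_heats(-1.0, 0.0)


class TestFreeEnergyChain:
    def test_reciprocal_critical_concentration(self):
        assert thermo.equilibrium_constant(7.5e-7) == pytest.approx(1.333e6, rel=1e-3)
        assert thermo.equilibrium_constant(1.0) == 1.0

    def test_free_energy_at_750_nM(self):
        # RT ln(750 nM) at 20 degC gives the apparent fibrillization dG
        assert thermo.free_energy(7.5e-7, 293.15) == pytest.approx(-34.36, abs=0.05)

    def test_standard_state_is_zero(self):
        assert thermo.free_energy(1.0, 293.15) == 0.0

    def test_micromolar_at_37C(self):
        assert thermo.free_energy(1e-6, 310.15) == pytest.approx(-35.62, abs=0.01)

    @given(log_c=st.floats(-9.0, 0.0))
    @settings(max_examples=50, deadline=None)
    def test_dG_from_K_F_and_from_conc_agree(self, log_c):
        c = 10.0 ** log_c
        t = 298.15
        via_k = -thermo.GAS_CONSTANT_J_PER_MOL_K * t * math.log(
            thermo.equilibrium_constant(c)) / 1000.0
        assert thermo.free_energy(c, t) == pytest.approx(via_k, rel=1e-9, abs=1e-15)

    def test_entropy_reproduces_printed_value(self):
        ds = thermo.entropy_gibbs_helmholtz(-297.74, -34.36, 293.15)
        assert ds == pytest.approx(-0.9, abs=0.01)
        assert ds == pytest.approx(-0.898, abs=0.001)

    def test_entropy_zero_when_dH_equals_dG(self):
        assert thermo.entropy_gibbs_helmholtz(-50.0, -50.0, 300.0) == 0.0

    def test_entropy_exact_arithmetic(self):
        assert thermo.entropy_gibbs_helmholtz(-100.0, -50.0, 250.0) \
            == pytest.approx(-0.2, rel=1e-12)


class TestHeatCapacityFit:
    def _table(self, bp, s_lo, s_hi, grid):
        df = synthgen.gen_dH_table(synthgen.SimSpec(
            "dH_table", {"breakpoint": bp, "slope_low": s_lo,
                         "slope_high": s_hi, "intercept": -297.74},
            np.asarray(grid, float)))
        return list(zip(df["T_K"], df["dH_kJ_mol"]))

    def test_two_phase_slopes_recovered_exactly(self):
        table = self._table(310.15, 113.84, -373.51,
                            [293.15, 298.15, 303.15, 308.15,
                             313.15, 318.15, 323.15, 333.15])
        fit = thermo.heat_capacity_fit(table, breakpoint=310.15)
        assert fit.dcp_low == pytest.approx(113.84, abs=1e-9)
        assert fit.dcp_high == pytest.approx(-373.51, abs=1e-9)

    def test_constant_enthalpy_zero_slopes(self):
        table = [(300.0, -100.0), (310.0, -100.0), (320.0, -100.0),
                 (330.0, -100.0)]
        fit = thermo.heat_capacity_fit(table, breakpoint=315.0)
        assert fit.dcp_low == pytest.approx(0.0, abs=1e-12)
        assert fit.dcp_high == pytest.approx(0.0, abs=1e-12)

    def test_single_branch_two_point_slope(self):
        with pytest.warns(UserWarning):
            fit = thermo.heat_capacity_fit([(300.0, -100.0), (310.0, -90.0)],
                                           breakpoint=320.0)
        assert fit.dcp_low == pytest.approx(1.0, rel=1e-12)
        assert math.isnan(fit.dcp_high)

    @pytest.mark.parametrize("bp", [305.0, 310.15, 318.0])
    def test_auto_breakpoint_exact_on_noise_free_input(self, bp):
        grid = np.linspace(293.0, 333.0, 11)
        table = self._table(bp, 113.84, -373.51, grid)
        fit = thermo.heat_capacity_fit(table, breakpoint="auto")
        assert fit.dcp_low == pytest.approx(113.84, abs=1e-6)
        assert fit.dcp_high == pytest.approx(-373.51, abs=1e-6)

    def test_identical_temperatures_rejected(self):
        with pytest.raises(InvalidParameterError):
            thermo.heat_capacity_fit([(300.0, -1.0), (300.0, -2.0)])


class TestThermoParams:
    def test_full_chain_satisfies_cross_identities(self):
        params = thermo.ThermoParams.from_measurements(
            critical_conc=7.5e-7, dH=-297.74, temperature=293.15,
            dCp=(113.84, -373.51))
        assert params.dG_app == pytest.approx(params.dH - params.T * params.dS,
                                              abs=1e-9)
        assert params.K_F * params.critical_conc == pytest.approx(1.0, rel=1e-12)
        assert params.dG_app == pytest.approx(-34.37, abs=0.01)

    def test_inconsistent_state_rejected(self):
        with pytest.raises(InvalidParameterError):
            thermo.ThermoParams(T=293.15, dG_app=-34.36, dH=-297.74, dS=0.9)


class TestStochasticCrystallization:
    def test_equilibrium_concentration_matches_detailed_balance(self):
        # k_diss/k_ass = 0.75/1e6 = 750 nM is the stationary free-unit level
        model = thermo.CrystallizationModel(
            k_ass=1e6, k_diss=0.75, n_fibrils=10, c0=1.5e-6,
            volume_scale=1e-15)
        traj = thermo.simulate_1d_crystallization(model, t_end=20000.0, seed=3)
        assert abs(traj.c_eq - 7.5e-7) <= 3.0 * traj.c_eq_se

    def test_irreversible_growth_depletes_free_units(self):
        model = thermo.CrystallizationModel(
            k_ass=1e6, k_diss=0.0, n_fibrils=10, c0=1e-6,
            volume_scale=1e-15)
        traj = thermo.simulate_1d_crystallization(model, t_end=5000.0, seed=1)
        assert traj.concentrations[-1] == 0.0
        # free-unit count never increases without dissociation
        assert np.all(np.diff(traj.concentrations) <= 1e-18)

    def test_balance_point_has_no_net_growth(self):
        model = thermo.CrystallizationModel(
            k_ass=1e6, k_diss=0.75, n_fibrils=10, c0=7.5e-7,
            volume_scale=1e-15)
        traj = thermo.simulate_1d_crystallization(model, t_end=5000.0, seed=5)
        # zero-drift random walk: net incorporation stays within 5 sigma
        assert abs(traj.fibril_mass[-1]) <= 5.0 * math.sqrt(traj.n_events)

    def test_larger_volume_tightens_the_estimate(self):
        common = dict(k_ass=1e6, k_diss=0.75, n_fibrils=10, c0=1.5e-6)
        small = thermo.simulate_1d_crystallization(
            thermo.CrystallizationModel(volume_scale=2.5e-16, **common),
            t_end=20000.0, seed=11)
        large = thermo.simulate_1d_crystallization(
            thermo.CrystallizationModel(volume_scale=2e-15, **common),
            t_end=20000.0, seed=11)
        for traj in (small, large):
            assert abs(traj.c_eq - 7.5e-7) <= 3.0 * traj.c_eq_se
        assert large.c_eq_se < small.c_eq_se

    def test_zero_fibrils_rejected(self):
        with pytest.raises(InvalidParameterError):
            thermo.CrystallizationModel(k_ass=1e6, k_diss=0.75, n_fibrils=0,
                                        c0=1e-6)
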