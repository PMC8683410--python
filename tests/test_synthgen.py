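"""Synthetic generators: forward-model values, noise determinism, errors."""

import numpy as np
import pytest

from fibrilkit import dls, synthgen
from fibrilkit.errors import InvalidParameterError


def _spec(kind, params, grid, noise_sd=0.0, seed=0):
    return synthgen.SimSpec(kind, params, np.asarray(grid, float), noise_sd, seed)


class TestSimSpec:
    @pytest.mark.parametrize("grid", [[1.0, 2.0], [1.0, 1.0, 2.0], [3.0, 2.0, 1.0]])
    def test_bad_grid_rejected(self, grid):
        with pytest.raises(InvalidParameterError):
            _spec("tht", {"k": 1.0}, grid)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidParameterError):
            _spec("tht", {"k": 1.0}, [1.0, 2.0, 3.0], noise_sd=-0.1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            _spec("spectrogram", {}, [1.0, 2.0, 3.0])


class TestNoiseDeterminism:
    def _generate(self, noise_sd, seed):
        """One representative output per generator family."""
        iso = synthgen.gen_isotherm(
            _spec("isotherm", {"k_d": 1e-7, "n": 2.0, "r_max": 100.0},
                  np.geomspace(1e-8, 1e-6, 12), noise_sd, seed))
        tht = synthgen.gen_tht(
            _spec("tht", {"f0": 1.0, "a": 10.0, "k": 1.5, "t50": 4.0},
                  np.linspace(0, 10, 40), noise_sd, seed))
        bu = synthgen.gen_buildup(
            _spec("buildup", {"t_m_s": 45.0}, [2.0, 5.0, 10.0, 50.0],
                  noise_sd, seed))
        return iso.responses, tht.fluorescence, bu.intensities

    def test_zero_noise_is_seed_independent(self):
        for a, b in zip(self._generate(0.0, 1), self._generate(0.0, 99)):
            np.testing.assert_array_equal(a, b)

    def test_noisy_output_reproducible_per_seed(self):
        same1 = self._generate(0.5, 7)
        same2 = self._generate(0.5, 7)
        other = self._generate(0.5, 8)
        for a, b, c in zip(same1, same2, other):
            np.testing.assert_array_equal(a, b)
            assert not np.array_equal(a, c)


class TestGenCorrelogram:
    def test_single_species_monotone_decay(self):
        trace = synthgen.gen_correlogram(
            _spec("correlogram", {"species": [(4.1, 1.0)]},
                  np.geomspace(1e-7, 1e-1, 100)),
            dls.InstrumentConfig(beta=0.9, temperature=310.15))
        assert np.all(np.diff(trace.g2m1) <= 0)
        assert trace.g2m1[0] == pytest.approx(0.9, rel=0.01)

    def test_empty_species_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_correlogram(
                _spec("correlogram", {"species": []}, [1e-6, 1e-5, 1e-4]))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_correlogram(
                _spec("correlogram", {"species": [(-4.1, 1.0)]},
                      [1e-6, 1e-5, 1e-4]))

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_correlogram(
                _spec("correlogram", {"species": [(4.1, 0.5), (17.2, 0.2)]},
                      [1e-6, 1e-5, 1e-4]))


class TestGenThermogram:
    def test_zero_pulses_flat_baseline(self):
        syn = synthgen.gen_thermogram(
            _spec("thermogram", {"baseline": 2.0, "pulses": [], "n_mol": 1e-7},
                  np.arange(0.0, 100.0, 1.0)))
        np.testing.assert_allclose(syn.thermogram.heat_flow, 2.0)
        assert syn.total_heat_J == 0.0

    def test_rectangle_heat_in_joules(self):
        # -5 ucal/s for 120 s = -600 ucal = -2.5104e-3 J
        syn = synthgen.gen_thermogram(
            _spec("thermogram",
                  {"baseline": 0.0, "pulses": [(50.0, 120.0, -5.0)],
                   "n_mol": 1e-7},
                  np.arange(0.0, 300.0, 0.5)))
        assert syn.total_heat_J == pytest.approx(-2.5104e-3, rel=1e-12)

    def test_pulse_outside_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_thermogram(
                _spec("thermogram",
                      {"baseline": 0.0, "pulses": [(90.0, 50.0, -5.0)],
                       "n_mol": 1e-7},
                      np.arange(0.0, 100.0, 1.0)))

    def test_gaussian_pulse_same_analytic_heat(self):
        spec = {"baseline": 0.0, "pulses": [(100.0, 120.0, -5.0)],
                "n_mol": 1e-7, "shape": "gauss"}
        syn = synthgen.gen_thermogram(
            _spec("thermogram", spec, np.arange(0.0, 400.0, 0.1)))
        assert syn.total_heat_J == pytest.approx(-2.5104e-3, rel=1e-12)
        # discretized Gaussian carries (almost) the same heat
        assert np.trapezoid(syn.thermogram.heat_flow, syn.thermogram.times) \
            == pytest.approx(-600.0, rel=5e-3)


class TestGenBuildup:
    def test_linear_values_evaluated_by_hand(self):
        bu = synthgen.gen_buildup(
            _spec("buildup", {"t_m_s": 45.0, "model": "linear_capped"},
                  [2.0, 5.0, 10.0]))
        np.testing.assert_allclose(bu.intensities,
                                   [2 / 45, 5 / 45, 10 / 45], rtol=1e-12)

    def test_cap_point_reaches_one(self):
        bu = synthgen.gen_buildup(
            _spec("buildup", {"t_m_s": 20.0, "model": "linear_capped"},
                  [10.0, 20.0, 40.0]))
        assert bu.intensities[1] == 1.0
        assert bu.intensities[2] == 1.0

    def test_exponential_asymptote(self):
        bu = synthgen.gen_buildup(
            _spec("buildup", {"t_m_s": 20.0, "model": "exponential"},
                  [10.0, 100.0, 10000.0]))
        assert bu.intensities[-1] == pytest.approx(1.0, abs=1e-9)


class TestGenIsotherm:
    def test_half_max_at_kd_for_any_hill_coefficient(self):
        for n in (0.5, 1.0, 2.4):
            kd = 31e-9
            iso = synthgen.gen_isotherm(
                _spec("isotherm", {"k_d": kd, "n": n, "r_max": 100.0},
                      [0.1 * kd, kd, 10 * kd]))
            assert iso.responses[1] == pytest.approx(50.0, rel=1e-12)

    def test_unit_hill_coefficient_is_langmuir(self):
        kd, rmax = 66e-9, 80.0
        grid = np.geomspace(1e-9, 1e-6, 15)
        iso = synthgen.gen_isotherm(
            _spec("isotherm", {"k_d": kd, "n": 1.0, "r_max": rmax}, grid))
        np.testing.assert_allclose(iso.responses, rmax * grid / (kd + grid),
                                   rtol=1e-12)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthgen.gen_isotherm(
                _spec("isotherm", {"k_d": 1e-7, "n": 1.0, "r_max": 1.0},
                      [-1e-8, 1e-7, 1e-6]))


class TestGenTht:
    def test_zero_amplitude_flat(self):
        tht = synthgen.gen_tht(
            _spec("tht", {"f0": 5.0, "a": 0.0, "k": 1.5, "t50": 4.0},
                  np.linspace(0, 10, 20)))
        np.testing.assert_allclose(tht.fluorescence, 5.0)

    def test_midpoint_value(self):
        tht = synthgen.gen_tht(
            _spec("tht", {"f0": 10.0, "a": 100.0, "k": 1.5, "t50": 4.0},
                  [0.0, 4.0, 10.0]))
        assert tht.fluorescence[1] == pytest.approx(60.0, rel=1e-12)

    def test_99_percent_of_plateau_at_logistic_quantile(self):
        # 99% of the amplitude is reached at t50 + ln(99)/k = 7.063 h
        t99 = 4.0 + np.log(99.0) / 1.5
        tht = synthgen.gen_tht(
            _spec("tht", {"f0": 0.0, "a": 1.0, "k": 1.5, "t50": 4.0},
                  [0.0, t99, 20.0]))
        assert tht.fluorescence[1] == pytest.approx(0.99, rel=1e-9)
        assert t99 == pytest.approx(7.06, abs=0.01)


class TestGenDHTable:
    def test_zero_slopes_constant_table(self):
        df = synthgen.gen_dH_table(
            _spec("dH_table", {"breakpoint": 310.0, "slope_low": 0.0,
                               "slope_high": 0.0, "intercept": -100.0},
                  [300.0, 310.0, 320.0]))
        np.testing.assert_allclose(df["dH_kJ_mol"], -100.0)

    def test_two_point_slope(self):
        with pytest.warns(UserWarning):  # single-phase: breakpoint above grid
            df = synthgen.gen_dH_table(
                _spec("dH_table", {"breakpoint": 325.0, "slope_low": 1.0,
                                   "slope_high": 0.0, "intercept": 0.0},
                      [300.0, 310.0, 320.0]))
        assert df["dH_kJ_mol"].iloc[2] - df["dH_kJ_mol"].iloc[0] \
            == pytest.approx(20.0, rel=1e-12)

    def test_breakpoint_outside_grid_warns(self):
        with pytest.warns(UserWarning):
            synthgen.gen_dH_table(
                _spec("dH_table", {"breakpoint": 400.0, "slope_low": 1.0,
                                   "slope_high": 2.0, "intercept": 0.0},
                      [300.0, 310.0, 320.0]))
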