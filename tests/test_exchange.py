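"""Unit and property tests for the EXSY exchange-kinetics module."""

import numpy as np
import pandas as pd
import pytest

from prolyquant import exchange
from prolyquant.exchange import (
    DEFAULT_MIXING_TIMES_S,
    InsufficientDataError,
    MixingSeries,
    build_ratio_series,
    equilibrium_cis_fraction,
    exsy_ratio_model,
    extract_peak_volume,
    fit_exchange,
    monte_carlo_errors,
    propagate_ratio_error,
    read_mixing_series,
)


class TestRatioModel:
    def test_zero_mixing_time_gives_zero(self):
        assert exsy_ratio_model(0.0, 3.0, 7.0) == 0.0

    def test_long_time_limit_equal_rates(self):
        assert exsy_ratio_model(1e3, 5.0, 5.0) == pytest.approx(1.0, rel=1e-12)

    def test_known_value(self):
        # frozen from independent high-precision evaluation of the ratio law
        assert exsy_ratio_model(0.1, 8.0, 4.65) == pytest.approx(0.3584019921, rel=1e-9)

    @pytest.mark.parametrize("k_ct,k_tc", [(0.0, 1.0), (1.0, -2.0), (-1.0, -1.0)])
    def test_nonpositive_rates_rejected(self, k_ct, k_tc):
        with pytest.raises(ValueError):
            exsy_ratio_model(0.1, k_ct, k_tc)

    def test_monotone_increasing_and_bounded(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k_ct, k_tc = rng.uniform(0.5, 50.0, size=2)
            # grid kept below floating-point saturation of the plateau
            t = np.linspace(1e-4, 5.0 / (k_ct + k_tc), 1000)
            r = exsy_ratio_model(t, k_ct, k_tc)
            assert np.all(np.diff(r) > 0)
            assert np.all(r < k_tc / k_ct)
            assert np.all(r >= 0)


class TestErrorPropagation:
    def test_zero_errors(self):
        assert propagate_ratio_error(10, 0, 5, 0) == 0.0

    def test_hand_value(self):
        assert propagate_ratio_error(10, 1, 5, 0.5) == pytest.approx(
            0.5 * np.sqrt(0.02), rel=1e-12
        )

    def test_finite_at_zero_cross_peak(self):
        # reduces to sigma_ct / I_tt instead of dividing by CT = 0
        assert propagate_ratio_error(10, 1, 0, 0.5) == pytest.approx(0.05)

    def test_zero_diagonal_raises(self):
        with pytest.raises(ZeroDivisionError):
            propagate_ratio_error(0, 1, 5, 0.5)

    def test_matches_textbook_form_when_positive(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            T, CT = rng.uniform(1, 100, 2)
            dT, dCT = rng.uniform(0.01, 5, 2)
            textbook = np.sqrt((dT / T) ** 2 + (dCT / CT) ** 2) * CT / T
            assert propagate_ratio_error(T, dT, CT, dCT) == pytest.approx(
                textbook, rel=1e-12
            )


class TestRatioSeries:
    def test_all_zero_cross_peaks(self):
        s = MixingSeries([0.1, 0.2, 0.3], [10, 9, 8], [0, 0, 0],
                         [1, 1, 1], [0.1, 0.1, 0.1])
        tab = build_ratio_series(s)
        assert np.all(tab["ratio"] == 0)

    def test_hand_ratios(self):
        s = MixingSeries([0.1, 0.2], [100, 50], [10, 20], [0, 0], [0, 0])
        tab = build_ratio_series(s)
        np.testing.assert_allclose(tab["ratio"], [0.1, 0.4])

    def test_forward_simulation_round_trip(self, noiseless_series):
        series, truth = noiseless_series
        tab = build_ratio_series(series)
        expected = exsy_ratio_model(np.asarray(tab["t_mix"]), 8.0, 4.65)
        np.testing.assert_allclose(tab["ratio"], expected, atol=1e-12)

    def test_zero_diagonal_names_mixing_time(self):
        s = MixingSeries([0.1, 0.2], [100, 0], [10, 20], [0, 0], [0, 0])
        with pytest.raises(ZeroDivisionError, match="0.2"):
            build_ratio_series(s)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            MixingSeries([0.2, 0.1], [1, 1], [1, 1], [0, 0], [0, 0])  # not increasing
        with pytest.raises(ValueError):
            MixingSeries([0.1, 0.2], [1, -1], [1, 1], [0, 0], [0, 0])  # negative volume
        with pytest.raises(ValueError):
            MixingSeries([0.1, 0.2], [1, 1], [1, 1], [0], [0, 0])  # length mismatch


class TestFitExchange:
    def test_round_trip_paper_regime(self, noiseless_series):
        series, _ = noiseless_series
        fit = fit_exchange(build_ratio_series(series))
        assert fit.converged
        assert fit.k_ct == pytest.approx(8.0, rel=1e-6)
        assert fit.k_tc == pytest.approx(4.65, rel=1e-6)
        assert fit.k_ex == pytest.approx(12.65, rel=1e-6)
        assert fit.k_ex == fit.k_ct + fit.k_tc

    def test_symmetric_round_trip(self):
        t = np.asarray(DEFAULT_MIXING_TIMES_S)
        tab = pd.DataFrame({"t_mix": t, "ratio": exsy_ratio_model(t, 5.0, 5.0)})
        fit = fit_exchange(tab)
        assert fit.k_ex == pytest.approx(10.0, rel=1e-6)

    def test_random_rate_recovery(self):
        rng = np.random.default_rng(7)
        t = np.asarray(DEFAULT_MIXING_TIMES_S)
        for _ in range(50):
            k_ct, k_tc = rng.uniform(0.5, 50.0, size=2)
            tab = pd.DataFrame({"t_mix": t, "ratio": exsy_ratio_model(t, k_ct, k_tc)})
            fit = fit_exchange(tab)
            assert fit.converged
            assert fit.k_ct == pytest.approx(k_ct, rel=1e-6)
            assert fit.k_tc == pytest.approx(k_tc, rel=1e-6)

    def test_insufficient_data(self):
        tab = pd.DataFrame({"t_mix": [0.1, 0.2], "ratio": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            fit_exchange(tab)

    def test_weighted_requires_positive_errors(self):
        t = np.asarray(DEFAULT_MIXING_TIMES_S)
        tab = pd.DataFrame({"t_mix": t, "ratio": exsy_ratio_model(t, 8.0, 4.65),
                            "ratio_error": np.zeros(t.size)})
        with pytest.raises(ValueError):
            fit_exchange(tab, weighted=True)
        # auto mode falls back to unweighted and still recovers
        fit = fit_exchange(tab)
        assert fit.k_ex == pytest.approx(12.65, rel=1e-6)

    def test_monte_carlo_errors_close_to_covariance(self):
        from prolyquant import synthetic

        series, _ = synthetic.gen_exsy_series(8.0, 4.65, noise_cv=0.02, seed=11)
        tab = build_ratio_series(series)
        fit = fit_exchange(tab, weighted=True)
        mc = monte_carlo_errors(tab, fit, n_draws=200, seed=12)
        assert mc["k_ex"] == pytest.approx(fit.se_k_ex, rel=0.35)


class TestEquilibriumCisFraction:
    def test_symmetry(self):
        fit = fit_exchange(pd.DataFrame({
            "t_mix": np.asarray(DEFAULT_MIXING_TIMES_S),
            "ratio": exsy_ratio_model(np.asarray(DEFAULT_MIXING_TIMES_S), 5.0, 5.0),
        }))
        assert equilibrium_cis_fraction(fit) == pytest.approx(0.5, rel=1e-6)

    def test_hand_value_and_long_time_consistency(self):
        t = np.asarray(DEFAULT_MIXING_TIMES_S)
        tab = pd.DataFrame({"t_mix": t, "ratio": exsy_ratio_model(t, 9.0, 1.0)})
        fit = fit_exchange(tab)
        assert equilibrium_cis_fraction(fit) == pytest.approx(0.1, rel=1e-5)
        # ratio at t = 100/k_ex has converged to the k_tc/k_ct plateau
        k_ex = 10.0
        assert exsy_ratio_model(100.0 / k_ex, 9.0, 1.0) == pytest.approx(
            1.0 / 9.0, abs=1e-9
        )

    def test_requires_convergence(self):
        from prolyquant.exchange import ExchangeFitResult

        bad = ExchangeFitResult(1, 1, 2, 0, 0, 0, 0, 5, converged=False)
        with pytest.raises(ValueError):
            equilibrium_cis_fraction(bad)


class TestPeakVolume:
    def _gaussian_grid(self, amp=100.0, c=(32.0, 40.0), w=(3.0, 4.0),
                      shape=(64, 80), base=0.0):
        ii, jj = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        g = amp * np.exp(-0.5 * (((ii - c[0]) / w[0]) ** 2 + ((jj - c[1]) / w[1]) ** 2))
        return g + base

    def test_recovers_analytic_volume(self):
        amp, w = 100.0, (3.0, 4.0)
        grid = self._gaussian_grid(amp=amp, w=w)
        pv = extract_peak_volume(grid, guess=(32, 40), window=20)
        assert pv.ok
        assert pv.volume == pytest.approx(2 * np.pi * amp * w[0] * w[1], rel=1e-6)

    def test_flat_baseline_offset_does_not_bias_volume(self):
        grid = self._gaussian_grid(base=7.5)
        pv = extract_peak_volume(grid, guess=(32, 40), window=20)
        assert pv.volume == pytest.approx(2 * np.pi * 100.0 * 12.0, rel=1e-6)

    def test_all_zero_grid_flagged(self):
        pv = extract_peak_volume(np.zeros((40, 40)), guess=(20, 20), window=10)
        assert not pv.ok

    def test_two_separated_peaks_window_isolates_first(self):
        grid = self._gaussian_grid(amp=100.0, c=(32.0, 20.0), w=(2.5, 2.5),
                                   shape=(64, 120))
        grid += self._gaussian_grid(amp=80.0, c=(32.0, 90.0), w=(2.5, 2.5),
                                    shape=(64, 120))
        pv = extract_peak_volume(grid, guess=(32, 20), window=15)
        # brute-force numerical integral of the first component over its window
        ii, jj = np.mgrid[17:48, 5:36].astype(float)
        ref = (100.0 * np.exp(-0.5 * (((ii - 32) / 2.5) ** 2 + ((jj - 20) / 2.5) ** 2))).sum()
        assert pv.volume == pytest.approx(ref, rel=0.01)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            extract_peak_volume(np.zeros((20, 20)), guess=(5, 5), window=10)


class TestIO:
    def test_read_mixing_series_converts_ms_to_s(self, tmp_path):
        p = tmp_path / "series.csv"
        p.write_text(
            "t_mix_ms,I_tt,I_ct,sigma_tt,sigma_ct\n"
            "12.5,100,1,1,0.1\n25,95,2,1,0.1\n50,90,4,1,0.1\n"
        )
        s = read_mixing_series(p)
        np.testing.assert_allclose(s.t_mix, [0.0125, 0.025, 0.050])
        assert len(s) == 3

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t_mix_ms,I_tt\n12.5,100\n")
        with pytest.raises(ValueError, match="I_ct"):
            read_mixing_series(p)
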