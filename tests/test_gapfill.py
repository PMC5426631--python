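"""Gap detection, baseline fills, period detection, and harmonic gap models."""

import numpy as np
import pandas as pd
import pytest

from tidalflux.gapfill import (
    GapLayout,
    detect_candidate_periods,
    evaluate_fill_methods,
    find_gaps,
    fit_gap_model,
    harmonic_fill,
    linear_fill,
    median_fill,
)
from tests.conftest import START, make_series


class TestMedianFill:
    def test_gap_takes_global_median(self):
        filled = median_fill(make_series([1, 2, 3, np.nan, 5]))
        assert filled.values[3] == 2.5
        assert filled.provenance[3] == "filled_median"

    def test_no_gaps_identity(self):
        s = make_series([1, 2, 3])
        filled = median_fill(s)
        assert np.array_equal(filled.values, s.values)
        assert list(filled.provenance) == ["observed"] * 3

    def test_interior_run_takes_k_copies(self):
        filled = median_fill(make_series([1, np.nan, np.nan, np.nan, 9]))
        assert list(filled.values[1:4]) == [5.0, 5.0, 5.0]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            median_fill(make_series([np.nan, np.nan]))


class TestLinearFill:
    def test_line_through_anchors(self):
        filled = linear_fill(make_series([0, np.nan, np.nan, 3]))
        assert list(filled.values) == [0.0, 1.0, 2.0, 3.0]

    def test_leading_gap_nearest_value(self):
        filled = linear_fill(make_series([np.nan, np.nan, 4, 5]))
        assert list(filled.values[:2]) == [4.0, 4.0]

    def test_matches_closed_form_line(self):
        rng = np.random.default_rng(3)
        v = rng.integers(0, 50, size=200).astype(float)
        miss = rng.random(200) < 0.3
        miss[[0, -1]] = False
        v[miss] = np.nan
        filled = linear_fill(make_series(v))
        obs_idx = np.flatnonzero(~miss)
        for i in np.flatnonzero(miss):
            lo = obs_idx[obs_idx < i].max()
            hi = obs_idx[obs_idx > i].min()
            expect = v[lo] + (v[hi] - v[lo]) * (i - lo) / (hi - lo)
            assert filled.values[i] == pytest.approx(expect, abs=1e-12)


class TestDetectCandidatePeriods:
    def test_single_planted_tone(self):
        t = np.arange(24 * 90, dtype=float)
        s = make_series(2 + np.sin(2 * np.pi * t / 24.0))
        periods = detect_candidate_periods(s, max_periods=1)
        n = len(t)
        bin_width_h = 24.0**2 / n  # one frequency-bin width at 24 h
        assert abs(periods[0] - 24.0) < bin_width_h

    def test_two_equal_tones_both_found(self):
        t = np.arange(24 * 90, dtype=float)
        s = make_series(4 + np.sin(2 * np.pi * t / 12.0) + np.sin(2 * np.pi * t / 24.0))
        periods = detect_candidate_periods(s, max_periods=2)
        assert {round(p) for p in periods} == {12, 24}

    def test_amplitudes_match_naive_dft_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(5, 1, size=256)
        s = make_series(np.clip(x, 0, None))
        periods = detect_candidate_periods(s, max_periods=4)
        xc = s.values - s.values.mean()
        n = len(xc)
        for p in periods:
            k = round(n / p)
            # direct-summation DFT at the detected frequency
            direct = np.abs(np.sum(xc * np.exp(-2j * np.pi * k * np.arange(n) / n)))
            fft_amp = np.abs(np.fft.rfft(xc))[k]
            assert abs(direct - fft_amp) < 1e-8

    def test_short_series_errors(self):
        with pytest.raises(ValueError):
            detect_candidate_periods(make_series([1, 2, 3]))

    def test_gappy_series_rejected(self):
        with pytest.raises(ValueError):
            detect_candidate_periods(make_series([1, np.nan, 3, 4]))


class TestFitGapModel:
    def test_exact_recovery_of_noiseless_sinusoid(self, sinusoid_series):
        series, truth = sinusoid_series
        gap = find_gaps(series).gaps[0]
        model, record = fit_gap_model(series, gap, [24.0])
        assert model.coef_sin[0] == pytest.approx(3.0, abs=1e-6)
        assert model.coef_cos[0] == pytest.approx(0.0, abs=1e-6)
        assert model.midline == pytest.approx(5.0, abs=1e-6)
        pred = model.predict(series.times[100:106])
        assert np.allclose(pred, truth[100:106], atol=1e-6)

    @pytest.mark.parametrize(
        "gap_hours,expected_ext", [(72, 72.0), (10, 48.0)],
        ids=["wide-gap-window-matches-gap", "narrow-gap-window-floor-48h"],
    )
    def test_window_is_max_of_gap_width_and_48h(self, gap_hours, expected_ext):
        v = np.full(24 * 30, 5.0)
        v[300:300 + gap_hours] = np.nan
        series = make_series(v)
        gap = find_gaps(series).gaps[0]
        model, record = fit_gap_model(series, gap, [24.0])
        ext = (gap[0] - model.fit_window[0]) / pd.Timedelta(hours=1)
        assert ext == expected_ext

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        t = np.arange(24 * 30, dtype=float)
        v = 10 + 2 * np.sin(2 * np.pi * t / 24) + rng.normal(0, 1, len(t))
        v = np.clip(v, 0, None)
        v[200:230] = np.nan
        series = make_series(v)
        gap = find_gaps(series).gaps[0]
        periods = [12.0, 24.0]
        model, record = fit_gap_model(series, gap, periods)
        # independent dense solve of the normal equations on the same design
        usable = ~np.isnan(v)
        win = (series.times >= model.fit_window[0]) & (series.times < model.fit_window[1])
        sel = usable & win
        th = t[sel]
        X = np.column_stack(
            [np.ones_like(th)]
            + [np.sin(2 * np.pi * th / p) for p in periods]
            + [np.cos(2 * np.pi * th / p) for p in periods]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ v[sel])
        got = np.concatenate([[model.midline], model.coef_sin, model.coef_cos])
        assert np.max(np.abs(got - beta)) < 1e-8

    def test_max_period_rule_excludes_long_periods(self):
        v = np.full(24 * 30, 5.0) + np.sin(np.arange(24 * 30) / 3.0)
        v[100:110] = np.nan
        series = make_series(np.clip(v, 0, None))
        gap = find_gaps(series).gaps[0]
        model, record = fit_gap_model(series, gap, [24.0, 10_000.0])
        assert 10_000.0 in record.periods_excluded
        assert all(p <= 2 * record.subset_hours for p in record.periods_retained)

    def test_all_periods_excluded_reduces_to_midline(self):
        v = np.full(24 * 10, 7.0)
        v[50:54] = np.nan
        series = make_series(v)
        gap = find_gaps(series).gaps[0]
        model, _ = fit_gap_model(series, gap, [10_000.0])
        assert len(model.periods) == 0
        assert model.midline == pytest.approx(7.0, abs=1e-9)

    def test_recovery_improves_with_subset_length(self):
        rng = np.random.default_rng(5)
        errs = []
        for days in (8, 60):
            t = np.arange(24 * days, dtype=float)
            v = 20 + 4 * np.sin(2 * np.pi * t / 24) + rng.normal(0, 2, len(t))
            v = np.clip(v, 0, None)
            mid = len(t) // 2
            v[mid:mid + 6] = np.nan
            series = make_series(v)
            gap = find_gaps(series).gaps[0]
            # widen the window beyond the floor so subset length tracks days
            model, _ = fit_gap_model(series, gap, [24.0], min_window_hours=24.0 * days)
            errs.append(abs(model.coef_sin[0] - 4.0) + abs(model.midline - 20.0))
        assert errs[1] < errs[0]


class TestHarmonicFill:
    def test_zero_residual_identical_for_any_seed(self, sinusoid_series):
        series, truth = sinusoid_series
        a, _ = harmonic_fill(series, [24.0], add_noise=True, seed=1)
        b, _ = harmonic_fill(series, [24.0], add_noise=True, seed=2)
        assert np.allclose(a.values, b.values, atol=1e-9)
        assert np.allclose(a.values[100:106], truth[100:106], atol=1e-6)

    def test_fixed_seed_bit_reproducible(self):
        rng = np.random.default_rng(0)
        v = np.clip(rng.normal(10, 3, 24 * 10), 0, None)
        v[60:80] = np.nan
        series = make_series(v)
        a, _ = harmonic_fill(series, [24.0], add_noise=True, seed=9)
        b, _ = harmonic_fill(series, [24.0], add_noise=True, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_injected_noise_sd_matches_residual_sd(self):
        # noisy base series so the fit has a well-defined residual sd
        rng = np.random.default_rng(11)
        t = np.arange(24 * 14, dtype=float)
        v = 50 + 10 * np.sin(2 * np.pi * t / 24) + rng.normal(0, 5, len(t))
        v = np.clip(v, 0, None)
        v[150:160] = np.nan
        series = make_series(v)
        base, report = harmonic_fill(series, [24.0], add_noise=False, seed=0)
        sd = report.records[0].model.residual_sd
        draws = []
        for seed in range(200):
            noisy, _ = harmonic_fill(series, [24.0], add_noise=True, seed=seed)
            draws.extend(noisy.values[150:160] - base.values[150:160])
        assert np.std(draws) == pytest.approx(sd, rel=0.10)

    def test_negative_predictions_clamped_to_zero(self):
        t = np.arange(24 * 10, dtype=float)
        v = np.clip(2 + 10 * np.sin(2 * np.pi * t / 24), 0, None)
        v[117:123] = np.nan  # gap over the sinusoid trough, model predicts < 0
        series = make_series(v)
        filled, _ = harmonic_fill(series, [24.0], add_noise=False, seed=0)
        assert filled.values.min() == 0.0
        assert np.all(filled.values >= 0)

    def test_fills_preserve_observed_values(self):
        rng = np.random.default_rng(2)
        v = np.clip(rng.normal(10, 3, 300), 0, None).round()
        v[40:60] = np.nan
        v[200:203] = np.nan
        series = make_series(v)
        for fill in (
            median_fill,
            linear_fill,
            lambda s: harmonic_fill(s, [24.0], seed=0)[0],
        ):
            filled = fill(series)
            obs = series.observed_mask
            assert np.array_equal(filled.values[obs], series.values[obs])
            assert not np.isnan(filled.values).any()
            assert len(filled) == len(series) and filled.start == series.start


class TestEvaluateFillMethods:
    def test_empty_layout_zero_inflation(self):
        rng = np.random.default_rng(4)
        truth = make_series(np.clip(rng.normal(20, 4, 24 * 30), 0, None).round())
        df = evaluate_fill_methods(
            truth, GapLayout(()), ["median", "linear"], [(10.0, 50.0)], n_rep=2, seed=0,
            candidate_periods=[24.0],
        )
        assert np.allclose(df["inflation"], 0.0)

    def test_inflation_matches_recomputation_from_spectra(self):
        from tidalflux.wavelet import WaveletConfig, morlet_cwt

        rng = np.random.default_rng(6)
        t = np.arange(24 * 40, dtype=float)
        v = np.clip(50 + 20 * np.sin(2 * np.pi * t / 24) + rng.normal(0, 5, len(t)), 0, None)
        truth = make_series(v)
        layout = GapLayout(((START + pd.Timedelta(hours=300),
                             START + pd.Timedelta(hours=360)),))
        band = (20.0, 30.0)
        config = WaveletConfig(voices_per_octave=8)
        df = evaluate_fill_methods(
            truth, layout, ["median"], [band], n_rep=1, seed=0,
            candidate_periods=[24.0], wavelet_config=config,
        )
        filled = median_fill(layout.mask(truth))
        spec_t = morlet_cwt(truth.values, 1.0, config)
        spec_f = morlet_cwt(filled.values, 1.0, config)
        in_band = (spec_t.periods >= band[0]) & (spec_t.periods <= band[1])
        usable = spec_t.outside_coi_mask()[:, in_band]
        expect = (spec_f.power[:, in_band] - spec_t.power[:, in_band])[usable].mean()
        assert df["inflation"].iloc[0] == pytest.approx(expect, rel=1e-9)

    def test_band_outside_grid_errors(self):
        truth = make_series(np.full(24 * 10, 5.0))
        with pytest.raises(ValueError):
            evaluate_fill_methods(
                truth, GapLayout(()), ["median"], [(1e6, 2e6)], n_rep=1, seed=0,
                candidate_periods=[24.0],
            )
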