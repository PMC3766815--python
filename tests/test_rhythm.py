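"""Correlogram correctness, rhythm-index classification, actograms, profiles."""

import numpy as np
import pytest

from circafly import (LightSchedule, actogram_matrix, analyze_rhythm,
                      autocorrelation, average_profile, ri_histogram)
from circafly.rhythm import RhythmResult
from circafly.synthetic import ActivitySimSpec, simulate_activity


def acf_oracle(x, max_lag):
    """Direct double-summation autocorrelation (biased normalization)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    denom = sum((xi - xbar) ** 2 for xi in x)
    out = []
    for k in range(max_lag + 1):
        s = 0.0
        for t in range(n - k):
            s += (x[t] - xbar) * (x[t + k] - xbar)
        out.append(s / denom)
    return np.array(out)


def test_correlogram_matches_double_sum_oracle(make_series):
    base = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1, 2, 1]
    s = make_series(base, bin_min=5)
    corr = autocorrelation(s, max_lag_h=4 * 5 / 60)
    np.testing.assert_allclose(corr.values[1:5], acf_oracle(base, 4)[1:5],
                               atol=1e-12)

    rng = np.random.default_rng(42)
    for _ in range(10):
        x = rng.poisson(3.0, size=rng.integers(100, 300))
        s = make_series(x, bin_min=5)
        max_lag = x.size // 2 - 1
        corr = autocorrelation(s, max_lag_h=max_lag * 5 / 60)
        np.testing.assert_allclose(corr.values, acf_oracle(x, max_lag),
                                   atol=1e-10)


def test_constant_series_flags_zero_variance(make_series):
    s = make_series([5] * 200, bin_min=5)
    corr = autocorrelation(s, max_lag_h=2.0)
    assert corr.zero_variance


def test_too_short_series_rejected(make_series):
    s = make_series(np.arange(100), bin_min=5)
    with pytest.raises(ValueError, match="reduce max_lag"):
        autocorrelation(s, max_lag_h=30.0)


def test_noise_free_cosine_peaks_at_circadian_lag(make_series):
    t_h = np.arange(7 * 288) * 5 / 60.0
    counts = np.round(50 * (1 + np.cos(2 * np.pi * t_h / 24.0))).astype(int)
    s = make_series(counts, bin_min=5)
    corr = autocorrelation(s, max_lag_h=30.0)
    lag24 = 24 * 60 // 5
    # the biased estimator's (N - k)/N taper drags the raw maximum a bin
    # or two early; after taper correction only the sub-bin finite-sum
    # ripple remains, so the local maximum sits within one bin of 288
    corrected = corr.values * corr.n_bins / (corr.n_bins - corr.lags)
    window = corrected[lag24 - 12 : lag24 + 13]
    assert abs(int(np.argmax(window)) - 12) <= 1
    raw_window = corr.values[lag24 - 12 : lag24 + 13]
    assert abs(int(np.argmax(raw_window)) - 12) <= 2
    res = analyze_rhythm(s)
    assert res.rhythmic and res.period_h == pytest.approx(24.0, abs=5 / 60)


def test_rhythmic_call_is_strictly_greater_than_threshold(make_series):
    t_h = np.arange(7 * 288) * 5 / 60.0
    counts = np.round(50 * (1 + np.cos(2 * np.pi * t_h / 24.0))).astype(int)
    s = make_series(counts, bin_min=5)
    ri = analyze_rhythm(s).ri
    at = analyze_rhythm(s, threshold=ri)
    below = analyze_rhythm(s, threshold=ri - 1e-9)
    assert not at.rhythmic      # RI exactly at threshold: arrhythmic
    assert below.rhythmic


def test_flag_handling_and_exclusions(make_series):
    rng = np.random.default_rng(0)
    counts = rng.poisson(3.0, 2016)
    status = np.ones(2016, dtype=int)
    status[:100] = 51            # <10% flagged: imputed, not excluded
    s = make_series(counts, bin_min=5, status=status)
    corr = autocorrelation(s, max_lag_h=30.0)
    assert corr.n_imputed == 100
    assert not analyze_rhythm(s).excluded

    status = np.ones(2016, dtype=int)
    status[:300] = 51            # >10% flagged: excluded
    s = make_series(counts, bin_min=5, status=status)
    res = analyze_rhythm(s)
    assert res.excluded and res.ri == 0.0 and not res.rhythmic


def test_dead_fly_excluded(make_series):
    counts = np.concatenate([np.random.default_rng(1).poisson(3.0, 1728),
                             np.zeros(288, dtype=int)])
    res = analyze_rhythm(make_series(counts, bin_min=5))
    assert res.excluded and "dead" in res.reason


def test_iid_poisson_flies_are_arrhythmic(make_series):
    rng = np.random.default_rng(5)
    ris = []
    for _ in range(50):
        s = make_series(rng.poisson(2.5, 2016), bin_min=5)
        ris.append(analyze_rhythm(s).ri)
    assert max(ris) < 0.2


def test_ri_histogram_examples():
    def res(ri):
        return RhythmResult("f", ri, 24.0, 24.0, ri > 0.2)

    hist = ri_histogram([res(0.05), res(0.05)])
    assert len(hist) == 1
    assert hist.iloc[0]["ri_lo"] == pytest.approx(0.0)
    assert hist.iloc[0]["frequency"] == 1.0

    hist = ri_histogram([res(0.05), res(0.25)])
    assert hist["frequency"].sum() == pytest.approx(1.0)
    by_lo = hist.set_index(hist["ri_lo"].round(6))["frequency"]
    assert by_lo[0.0] == 0.5 and by_lo[0.2] == 0.5

    with pytest.raises(ValueError, match="no non-excluded"):
        ri_histogram([RhythmResult("f", 0, None, None, False, True, "dead")])


def test_ri_histogram_bimodal_with_planted_mixture():
    spec = ActivitySimSpec(n_flies=64, fraction_rhythmic=0.5, n_days_ld=0,
                           n_days_dd=7, seed=11)
    series, truth = simulate_activity(spec)
    results = [analyze_rhythm(s) for s in series]
    hist = ri_histogram(results)
    above = hist.loc[hist["ri_lo"] >= 0.2, "frequency"].sum()
    # mass above the threshold within a 3-sigma binomial band of 0.5
    assert abs(above - 0.5) <= 3 * np.sqrt(0.25 / 64)


def test_actogram_shapes_and_conservation(make_series):
    counts = np.arange(2 * 288)
    s = make_series(counts, bin_min=5)
    mat = actogram_matrix(s, double_plot=True)
    assert mat.shape == (2, 2 * 288)
    assert np.isnan(mat[1, 288:]).all()        # last row half-padded
    single = actogram_matrix(s, double_plot=False)
    assert single.shape == (2, 288)
    assert np.nansum(single) == counts.sum()
    assert np.nansum(mat[:, :288]) == counts.sum()


def test_actogram_peak_drift_tracks_period(make_series):
    for period_h, expected_drift in [(24.0, 0), (25.0, 12)]:
        t_h = np.arange(6 * 288) * 5 / 60.0
        counts = np.round(
            10000 * np.maximum(0, np.cos(2 * np.pi * t_h / period_h))
        ).astype(int)
        mat = actogram_matrix(make_series(counts, bin_min=5),
                              double_plot=False)
        peaks = np.nanargmax(mat, axis=1)
        drifts = np.diff(peaks)
        assert all(d == expected_drift for d in drifts)


def test_average_profile_flat_and_planted_peak(make_series):
    flat = make_series(np.full(2 * 288, 7), bin_min=5)
    prof = average_profile([flat])
    np.testing.assert_allclose(prof["mean"], 7.0)

    # noise-free rectified-cosine with planted acrophase at ZT6: the folded
    # profile must peak in the bin containing the planted phase
    t_h = np.arange(7 * 288) * 5 / 60.0
    counts = np.round(
        10000 * np.maximum(0, np.cos(2 * np.pi * (t_h - 6.0) / 24.0))
    ).astype(int)
    prof = average_profile([make_series(counts, bin_min=5)])
    peak_h = prof.loc[prof["mean"].idxmax(), "time_h"]
    assert abs(peak_h - 6.0) <= 5 / 60 + 1e-9


def test_average_profile_errors(make_series):
    with pytest.raises(ValueError, match="empty"):
        average_profile([])
    a = make_series(np.ones(288, dtype=int), bin_min=5)
    b = make_series(np.ones(1440, dtype=int), bin_min=1)
    with pytest.raises(ValueError, match="mixed bin widths"):
        average_profile([a, b])
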