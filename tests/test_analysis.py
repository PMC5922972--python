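"""Feature extraction: normalization, peaks, filtering, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoclock.analysis import (
    condition_summary,
    cycle_features,
    detect_peaks_troughs,
    filter_tracks,
    mad,
    normalize_background,
    period_drift,
    size_band_summary,
    trajectory_features,
)


def triangle_wave(times, period=20.0, phase=0.0):
    x = ((times - phase) % period) / period
    return np.where(x < 0.5, 2 * x, 2 - 2 * x)


def test_normalize_identity_background():
    sig = np.array([1.0, 2.0, 3.0])
    assert np.array_equal(normalize_background(sig, np.ones(3)), sig)


def test_normalize_cancels_common_drift():
    t = np.arange(200.0)
    drift = 1.0 + 0.002 * t
    sig = (50 + 10 * np.sin(t / 5)) * drift
    out = normalize_background(sig, 100.0 * drift)
    expected = (50 + 10 * np.sin(t / 5)) / 100.0
    assert np.allclose(out, expected)


def test_normalize_reduces_linear_drift_slope():
    """10%/day drift leaves < 1% of amplitude as residual trend."""
    t = np.arange(0.0, 2880.0, 7.5)  # two days of frames
    drift = 1.0 + (0.1 / 1440.0) * t
    clean = 100 + 30 * np.sin(2 * np.pi * t / 60.0)
    out = normalize_background(clean * drift, 80.0 * drift)
    slope = np.polyfit(t, out, 1)[0]
    slope_ref = np.polyfit(t, clean / 80.0, 1)[0]  # drift-free reference
    drift_slope = np.polyfit(t, clean * drift / 80.0, 1)[0]
    amplitude = 30 / 80.0
    # normalization removes the drift contribution to the trend
    assert abs((slope - slope_ref) * t[-1]) < 0.01 * amplitude
    assert abs(drift_slope) > 10 * abs(slope - slope_ref)


def test_normalize_rejects_nonpositive_background():
    with pytest.raises(ValueError):
        normalize_background(np.ones(3), np.array([1.0, 0.0, 1.0]))


def test_peaks_on_noiseless_triangle_wave():
    t = np.arange(0.0, 61.0, 1.0)
    sig = triangle_wave(t, period=20.0, phase=0.0)
    peaks, troughs = detect_peaks_troughs(sig)
    assert list(t[peaks]) == [10.0, 30.0, 50.0]
    feats = cycle_features(t, sig)
    assert np.allclose(feats.periods, [20.0, 20.0])


def test_constant_signal_has_no_peaks():
    peaks, troughs = detect_peaks_troughs(np.full(100, 3.0))
    assert len(peaks) == 0 and len(troughs) == 0


def test_peaks_alternate_with_troughs():
    t = np.arange(0.0, 300.0, 1.0)
    rng = np.random.default_rng(0)
    sig = np.sin(2 * np.pi * t / 40.0) + 0.05 * rng.normal(size=len(t))
    peaks, troughs = detect_peaks_troughs(sig)
    events = sorted([(i, "p") for i in peaks] + [(i, "t") for i in troughs])
    kinds = [k for _, k in events]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))


def test_noisy_sawtooth_period_recovery():
    """Mean absolute period error < 1 frame at SNR 10 over 100 replicates."""
    period, n_frames = 8, 200  # 8 frames per cycle
    t = np.arange(n_frames, dtype=float)
    saw = (t % period) / period
    errs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sig = saw + 0.1 * rng.normal(size=n_frames)
        feats = cycle_features(t, sig)
        if len(feats.periods):
            errs.append(np.mean(np.abs(feats.periods - period)))
    assert len(errs) > 90
    assert np.mean(errs) < 1.0


def test_single_peak_trace_boundary():
    t = np.arange(0.0, 21.0, 1.0)
    sig = np.exp(-((t - 10.0) ** 2) / 4.0)
    feats = cycle_features(t, sig)
    assert feats.n_cycles == 1
    assert len(feats.periods) == 0


def test_filter_tracks_boundary():
    t = np.arange(0.0, 100.0, 1.0)
    one = cycle_features(t[:25], triangle_wave(t[:25]), droplet_id="one")  # 1 peak
    two = cycle_features(t[:45], triangle_wave(t[:45]), droplet_id="two")  # 2 peaks
    assert one.n_cycles == 1 and two.n_cycles == 2
    kept = filter_tracks([one, two])
    assert [f.droplet_id for f in kept] == ["two"]
    assert filter_tracks([]) == []


def test_mad_examples():
    assert mad([1, 2, 3, 4, 5]) == 1.0
    assert mad([7.0] * 10) == 0.0


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
    st.floats(-1e6, 1e6),
)
def test_mad_translation_invariance(values, shift):
    assert mad(np.asarray(values) + shift) == pytest.approx(mad(values), abs=1e-6)


def _features_with_periods(did, periods, cond=0.0):
    periods = np.asarray(periods, dtype=float)
    peaks = np.concatenate([[0.0], np.cumsum(periods)])
    f = cycle_features(
        np.arange(0.0, peaks[-1] + 21.0, 1.0),
        np.zeros(int(peaks[-1]) + 21),
        detections=(np.array([], dtype=int), np.array([], dtype=int)),
        droplet_id=did,
    )
    f.peak_times = peaks
    f.periods = periods
    f.n_cycles = len(peaks)
    f.meta["condition"] = cond
    return f


def test_condition_summary_single_droplet():
    f = _features_with_periods("a", [40.0, 42.0])
    tab = condition_summary({"c0": [f]})
    row = tab.iloc[0]
    assert row["median_period_min"] == pytest.approx(41.0)
    assert row["mad_period_min"] == 0.0
    assert row["median_n_cycles"] == 3


def test_condition_summary_permutation_invariant():
    feats = [_features_with_periods(i, [30.0 + i, 32.0 + i]) for i in range(6)]
    a = condition_summary({"c": feats})
    b = condition_summary({"c": feats[::-1]})
    assert a.drop(columns=["condition"]).equals(b.drop(columns=["condition"]))


def test_size_band_constant_statistic_collapses():
    diam = np.linspace(20, 300, 200)
    tab = size_band_summary(diam, np.full(200, 55.0))
    assert np.allclose(tab["q25"], 55.0) and np.allclose(tab["q75"], 55.0)
    assert np.allclose(tab["band_width"], 0.0)


def test_size_band_single_bin_fallback():
    tab = size_band_summary(np.linspace(30, 60, 20), np.arange(20.0))
    assert len(tab) == 1


def test_size_band_defaults_window20_bin50():
    import inspect

    sig = inspect.signature(size_band_summary)
    assert sig.parameters["window"].default == 20
    assert sig.parameters["bin_size"].default == 50


def test_size_band_detects_heteroscedasticity():
    """Band is wider where the statistic is noisier (small droplets)."""
    rng = np.random.default_rng(42)
    diam = np.sort(rng.uniform(20, 300, 400))
    spread = np.where(diam < 100, 30.0, 5.0)
    stat = 60.0 + spread * rng.standard_normal(400)
    tab = size_band_summary(diam, stat)
    assert tab["band_width"].iloc[0] > tab["band_width"].iloc[-1]


def test_period_drift_flat_and_rising():
    flat = _features_with_periods("flat", [40.0] * 8)
    rising = _features_with_periods("up", 40.0 + 2.0 * np.arange(8))
    tab = period_drift([flat, rising])
    tau_flat = tab.set_index("droplet_id").loc["flat", "kendall_tau"]
    tau_up = tab.set_index("droplet_id").loc["up", "kendall_tau"]
    assert np.isnan(tau_flat)  # no variation -> no defined trend
    assert tau_up == pytest.approx(1.0)
    pooled = tab.attrs["pooled"]
    assert list(pooled["cycle_index"]) == list(range(8))


def test_trajectory_features_match_integrator_period(osc_trajectory):
    """Post-transient feature period agrees with peak spacing to one step."""
    feats = trajectory_features(osc_trajectory.times, osc_trajectory.cyclin_b)
    peaks, _ = detect_peaks_troughs(osc_trajectory.cyclin_b)
    raw_periods = np.diff(osc_trajectory.times[peaks])
    assert abs(feats["period"] - np.median(raw_periods[2:])) <= 1.0
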