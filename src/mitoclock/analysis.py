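"""Oscillation feature extraction and population summaries.

Turns per-droplet intensity (or model concentration) time series into
per-cycle features — periods, amplitudes, baselines — and aggregates them
across droplet populations the way droplet time-lapse studies report them:
background-normalised traces, peak/trough detection with automated pruning,
a minimum-of-two-oscillations track filter, medians with MAD error bars per
condition, and LOWESS-smoothed running percentile bands versus droplet size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import kendalltau
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "CycleFeatures",
    "normalize_background",
    "detect_peaks_troughs",
    "cycle_features",
    "filter_tracks",
    "mad",
    "condition_summary",
    "size_band_summary",
    "period_drift",
    "trajectory_features",
]

#: default peak prominence as a fraction of the global signal range
DEFAULT_PROMINENCE_FRAC = 0.10
#: default minimum peak separation in frames
DEFAULT_MIN_SEPARATION = 3


@dataclass
class CycleFeatures:
    """Per-cycle oscillation features of a single track.

    ``periods`` are successive peak-to-peak intervals (min); ``amplitudes``
    are peak value minus the preceding trough value; ``baselines`` are the
    trough values themselves.  ``n_cycles`` counts detected peaks.
    """

    droplet_id: str | int
    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray
    periods: np.ndarray
    amplitudes: np.ndarray
    baselines: np.ndarray
    n_cycles: int
    meta: dict = field(default_factory=dict)


def normalize_background(signal, background=None):
    """Divide a channel intensity by the background intensity pointwise.

    Compensates multiplicative intensity drift over time: if both signal and
    background carry the same drift factor g(t), the ratio is drift-free.
    Accepts either a droplet trace object (with ``channels`` and
    ``background`` attributes) or two arrays.
    """
    if background is None:  # FluorescenceTrace-like object
        trace = signal
        return {
            name: np.asarray(ch, dtype=float) / np.asarray(trace.background, dtype=float)
            for name, ch in trace.channels.items()
        }
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background intensities must be positive")
    return signal / background


def _enforce_alternation(signal, peaks, troughs):
    """Prune extrema so peaks and troughs strictly alternate.

    Between consecutive peaks the lowest trough is kept; between consecutive
    troughs the highest peak is kept.  Deterministic for fixed inputs.
    """
    events = [(i, +1) for i in peaks] + [(i, -1) for i in troughs]
    events.sort()
    pruned: list[tuple[int, int]] = []
    for idx, kind in events:
        if pruned and pruned[-1][1] == kind:
            prev_idx, _ = pruned[-1]
            if kind == +1:  # two peaks in a row: keep higher
                if signal[idx] > signal[prev_idx]:
                    pruned[-1] = (idx, kind)
            else:  # two troughs in a row: keep lower
                if signal[idx] < signal[prev_idx]:
                    pruned[-1] = (idx, kind)
        else:
            pruned.append((idx, kind))
    new_peaks = np.array([i for i, k in pruned if k == +1], dtype=int)
    new_troughs = np.array([i for i, k in pruned if k == -1], dtype=int)
    return new_peaks, new_troughs


def detect_peaks_troughs(
    signal,
    min_prominence: float | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect alternating peak and trough indices in a uniformly sampled signal.

    Automated stand-in for manual peak curation: extrema with prominence
    below ``min_prominence`` (default 10% of the global signal range) or
    closer than ``min_separation`` frames are pruned, then alternation is
    enforced by keeping the extremal point between neighbours.
    """
    signal = np.asarray(signal, dtype=float)
    rng = float(np.max(signal) - np.min(signal)) if signal.size else 0.0
    if rng == 0.0:
        return np.array([], dtype=int), np.array([], dtype=int)
    if min_prominence is None:
        min_prominence = DEFAULT_PROMINENCE_FRAC * rng
    peaks, _ = find_peaks(signal, prominence=min_prominence, distance=min_separation)
    troughs, _ = find_peaks(-signal, prominence=min_prominence, distance=min_separation)
    return _enforce_alternation(signal, peaks, troughs)


def cycle_features(
    times,
    signal,
    detections: tuple[np.ndarray, np.ndarray] | None = None,
    droplet_id: str | int = 0,
    **detect_kwargs,
) -> CycleFeatures:
    """Derive per-cycle features from a track and its peak/trough detections.

    Amplitude of cycle i is peak_i minus the immediately preceding trough
    value; its baseline is that trough value.  Peaks without a preceding
    trough contribute to the cycle count and periods but not to
    amplitude/baseline.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if detections is None:
        detections = detect_peaks_troughs(signal, **detect_kwargs)
    peaks, troughs = detections
    periods = np.diff(times[peaks]) if len(peaks) >= 2 else np.array([])
    amplitudes, baselines = [], []
    for pk in peaks:
        prior = troughs[troughs < pk]
        if len(prior):
            tr = prior[-1]
            amplitudes.append(signal[pk] - signal[tr])
            baselines.append(signal[tr])
    return CycleFeatures(
        droplet_id=droplet_id,
        peak_times=times[peaks],
        trough_times=times[troughs],
        peak_values=signal[peaks],
        trough_values=signal[troughs],
        periods=periods,
        amplitudes=np.asarray(amplitudes, dtype=float),
        baselines=np.asarray(baselines, dtype=float),
        n_cycles=len(peaks),
    )


def filter_tracks(features_list: Iterable[CycleFeatures], min_cycles: int = 2) -> list[CycleFeatures]:
    """Discard tracks with fewer than ``min_cycles`` detected oscillations."""
    return [f for f in features_list if f.n_cycles >= min_cycles]


def mad(values) -> float:
    """Median absolute deviation, unscaled: median(|x - median(x)|)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan")
    return float(np.median(np.abs(values - np.median(values))))


def condition_summary(features_by_condition: dict) -> pd.DataFrame:
    """Median period/cycle count with MAD error bars per condition.

    ``features_by_condition`` maps a condition label to a list of
    CycleFeatures (pooled across replicates).  Per-droplet period is the
    mean of that droplet's cycle periods; the summary is the median over
    droplets, order-invariant by construction.
    """
    rows = []
    for cond, feats in features_by_condition.items():
        per_droplet_period = [float(np.mean(f.periods)) for f in feats if len(f.periods)]
        cycle_counts = [f.n_cycles for f in feats]
        rows.append(
            {
                "condition": cond,
                "n_droplets": len(feats),
                "median_period_min": float(np.median(per_droplet_period)) if per_droplet_period else np.nan,
                "mad_period_min": mad(per_droplet_period) if per_droplet_period else np.nan,
                "median_n_cycles": float(np.median(cycle_counts)) if cycle_counts else np.nan,
                "mad_n_cycles": mad(cycle_counts) if cycle_counts else np.nan,
            }
        )
    return pd.DataFrame(rows)


def size_band_summary(
    equivalent_diameters,
    statistic,
    window: int = 20,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Smoothed 25th–75th percentile band of a per-droplet statistic vs size.

    Droplets are sorted by equivalent diameter; running 25th/50th/75th
    percentiles are computed over ``bin_size``-droplet bins (linear
    interpolation quartiles; a remainder bin smaller than ``bin_size`` is
    merged into the last full bin), then each band edge is smoothed by
    locally weighted regression over ``window``-point neighbourhoods.
    With fewer than ``bin_size`` droplets a single bin covers all of them.
    """
    diam = np.asarray(equivalent_diameters, dtype=float)
    stat = np.asarray(statistic, dtype=float)
    if diam.shape != stat.shape:
        raise ValueError("diameters and statistic must have equal length")
    order = np.argsort(diam, kind="stable")
    diam, stat = diam[order], stat[order]
    n = len(diam)
    if n == 0:
        return pd.DataFrame(columns=["diameter_um", "q25", "q50", "q75", "q25_smooth", "q75_smooth"])

    starts = list(range(0, n, bin_size))
    # merge a short remainder into the last full bin
    if len(starts) > 1 and n - starts[-1] < bin_size:
        starts = starts[:-1]
    rows = []
    for i, s in enumerate(starts):
        e = n if i == len(starts) - 1 else s + bin_size
        chunk = stat[s:e]
        rows.append(
            {
                "diameter_um": float(np.median(diam[s:e])),
                "q25": float(np.percentile(chunk, 25)),
                "q50": float(np.percentile(chunk, 50)),
                "q75": float(np.percentile(chunk, 75)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        frac = min(1.0, window / len(df))
        for col in ("q25", "q75"):
            sm = _sm_lowess(df[col].to_numpy(), df["diameter_um"].to_numpy(), frac=frac, return_sorted=False)
            df[f"{col}_smooth"] = sm
    else:
        df["q25_smooth"] = df["q25"]
        df["q75_smooth"] = df["q75"]
    df["band_width"] = df["q75"] - df["q25"]
    return df


def period_drift(features_list: Iterable[CycleFeatures]) -> pd.DataFrame:
    """Per-cycle-index period trend, per droplet and pooled.

    Returns a table with one row per droplet: its Kendall tau of period
    versus cycle index (NaN when fewer than 2 periods), plus pooled median
    period per cycle index in the attached ``attrs['pooled']`` frame.
    """
    rows = []
    pooled: dict[int, list[float]] = {}
    for f in features_list:
        periods = np.asarray(f.periods, dtype=float)
        for i, p in enumerate(periods):
            pooled.setdefault(i, []).append(float(p))
        if len(periods) >= 2 and np.ptp(periods) > 0:
            tau = kendalltau(np.arange(len(periods)), periods).statistic
        else:
            tau = np.nan
        rows.append({"droplet_id": f.droplet_id, "n_periods": len(periods), "kendall_tau": tau})
    df = pd.DataFrame(rows)
    pooled_df = pd.DataFrame(
        {
            "cycle_index": sorted(pooled),
            "median_period_min": [float(np.median(pooled[i])) for i in sorted(pooled)],
            "n": [len(pooled[i]) for i in sorted(pooled)],
        }
    )
    df.attrs["pooled"] = pooled_df
    return df


def trajectory_features(
    times,
    signal,
    discard_before_peak: int = 2,
    **detect_kwargs,
) -> dict:
    """Post-transient summary (period/amplitude/baseline means) of one series.

    The transient is removed by discarding everything before the
    ``discard_before_peak``-th detected peak, then features are recomputed
    on the remainder.  Returns NaNs when fewer than two post-transient
    peaks remain (no sustained oscillation).
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    peaks, _ = detect_peaks_troughs(signal, **detect_kwargs)
    out = {"period": np.nan, "amplitude": np.nan, "baseline": np.nan, "n_cycles": 0}
    if len(peaks) < discard_before_peak:
        return out
    start = peaks[discard_before_peak - 1]
    feats = cycle_features(times[start:], signal[start:], **detect_kwargs)
    out["n_cycles"] = feats.n_cycles
    if len(feats.periods):
        out["period"] = float(np.mean(feats.periods))
    if len(feats.amplitudes):
        out["amplitude"] = float(np.mean(feats.amplitudes))
        out["baseline"] = float(np.mean(feats.baselines))
    return out
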