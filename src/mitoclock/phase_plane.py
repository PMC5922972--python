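"""Nullclines, fixed points, stability, and regime classification vs r.

The cyclin B nullcline ``B = ksy / kdeg(c)`` is independent of the feedback
balance r; the Cdk1 nullcline shifts with r.  Their intersections are fixed
points whose stability (from the analytic Jacobian) together with long-run
simulated amplitude classifies the dynamical regime: a low stable steady
state of cyclin B, sustained limit-cycle oscillations, or a high stable
steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .analysis import trajectory_features
from .core_model import (
    ConcState,
    RateParams,
    cdc25_rate,
    degradation_rate,
    odes_rhs,
    simulate_deterministic,
    wee1_rate,
)

__all__ = [
    "FixedPoint",
    "cyclin_nullcline",
    "cdk1_nullcline",
    "find_fixed_points",
    "jacobian",
    "classify_regime",
    "sweep_r",
]

#: amplitude (nM) below which a long-run trajectory counts as non-oscillatory
OSCILLATION_AMPLITUDE_THRESHOLD = 1.0
#: cyclin B level (nM) separating the low and high stable steady states
LOW_HIGH_SPLIT_NM = 60.0
#: |Re(eigenvalue)| below this (1/min) is treated as marginal
MARGINAL_TOL = 1e-6
#: fixed points closer than this (nM) are deduplicated
DEDUP_TOL = 1e-4


@dataclass
class FixedPoint:
    """A nullcline intersection with its linear stability."""

    state: ConcState
    eigenvalues: tuple[complex, complex]
    stability: str  # stable | unstable | marginal


def cyclin_nullcline(cdk1a_grid, p: RateParams):
    """Cyclin B values where d[CyclinB]/dt = 0: ksy / kdeg(cdk1a)."""
    grid = np.asarray(cdk1a_grid, dtype=float)
    return p.ksy / degradation_rate(grid, p)


def cdk1_nullcline(cdk1a_grid, p: RateParams):
    """Cyclin B values where d[Cdk1a]/dt = 0, solved algebraically.

    B = c + (kwee1(c)·c + kdeg(c)·c − ksy) / kcdc25(c).  Points where the
    Cdc25 rate vanishes are returned as NaN rather than silently dropped
    (cannot occur with a positive basal a_cdc25).
    """
    grid = np.asarray(cdk1a_grid, dtype=float)
    kw = wee1_rate(grid, p)
    kd = degradation_rate(grid, p)
    kc = cdc25_rate(grid, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = grid + (kw * grid + kd * grid - p.ksy) / kc
    out = np.where(kc == 0.0, np.nan, out)
    return out


def _hill_up_deriv(x, b, n, ec50):
    x = np.asarray(x, dtype=float)
    q = (x / ec50) ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = b * n * q / (x * (q + 1.0) ** 2)
    return np.where(x == 0.0, 0.0, d)


def jacobian(state: ConcState | tuple[float, float], p: RateParams) -> np.ndarray:
    """Analytic Jacobian of the rate laws at a state, order (cyclin_b, cdk1a)."""
    if isinstance(state, ConcState):
        cyc, act = state.cyclin_b, state.cdk1a
    else:
        cyc, act = state
    kdeg = degradation_rate(act, p)
    kw = wee1_rate(act, p)
    kc = cdc25_rate(act, p)
    dkdeg = float(_hill_up_deriv(act, p.b_deg, p.n_deg, p.ec50_deg))
    dkw = -np.sqrt(p.r) * float(_hill_up_deriv(act, p.b_wee1, p.n_wee1, p.ec50_wee1))
    dkc = (1.0 / np.sqrt(p.r)) * float(_hill_up_deriv(act, p.b_cdc25, p.n_cdc25, p.ec50_cdc25))
    return np.array(
        [
            [-kdeg, -dkdeg * cyc],
            [kc, dkc * (cyc - act) - kc - dkw * act - kw - dkdeg * act - kdeg],
        ]
    )


def _stability_label(eigs, tol: float = MARGINAL_TOL) -> str:
    re_max = max(e.real for e in eigs)
    if abs(re_max) < tol:
        return "marginal"
    return "unstable" if re_max > 0 else "stable"


def find_fixed_points(
    p: RateParams,
    domain: tuple[float, float] = (0.0, 120.0),
    grid_n: int = 4000,
) -> list[FixedPoint]:
    """All nullcline intersections with Cdk1a in ``domain``.

    Roots of (cyclin nullcline − Cdk1 nullcline) are bracketed on a dense
    grid and refined by Brent's method, deduplicated within a small
    tolerance, then labelled via the analytic Jacobian's eigenvalues.
    """

    def gap(c):
        return float(cyclin_nullcline(c, p) - cdk1_nullcline(c, p))

    lo = max(domain[0], 1e-9)
    grid = np.linspace(lo, domain[1], grid_n)
    vals = np.array([gap(c) for c in grid])
    roots: list[float] = []
    sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        roots.append(brentq(gap, grid[i], grid[i + 1], xtol=1e-12))
    for i in np.where(vals == 0.0)[0]:
        roots.append(float(grid[i]))
    roots.sort()
    deduped: list[float] = []
    for c in roots:
        if not deduped or abs(c - deduped[-1]) > DEDUP_TOL:
            deduped.append(c)
    out = []
    for c in deduped:
        cyc = float(cyclin_nullcline(c, p))
        if not (domain[0] <= cyc <= domain[1] * 1.5):
            continue
        eigs = tuple(np.linalg.eigvals(jacobian((cyc, c), p)))
        out.append(FixedPoint(state=ConcState(cyc, min(c, cyc)), eigenvalues=eigs, stability=_stability_label(eigs)))
    return out


def classify_regime(
    p: RateParams,
    t_end: float = 3000.0,
    amplitude_threshold: float = OSCILLATION_AMPLITUDE_THRESHOLD,
) -> str:
    """Label the dynamical regime as stable_low / oscillatory / stable_high.

    A long simulation from the (0, 0) origin is examined post-transient: a
    peak-to-trough amplitude above ``amplitude_threshold`` sustained over
    the last three cycles means a limit cycle; otherwise the attractor's
    cyclin B level relative to ``LOW_HIGH_SPLIT_NM`` separates the
    Cdc25-dominated low state from the Wee1-dominated high state.
    """
    traj = simulate_deterministic(p, (0.0, 0.0), t_end=t_end, dt_out=1.0)
    half = len(traj.times) // 2
    from .analysis import detect_peaks_troughs

    peaks, troughs = detect_peaks_troughs(traj.cyclin_b[half:])
    if len(peaks) >= 4 and len(troughs) >= 3:
        last_amps = []
        for pk in peaks[-3:]:
            prior = troughs[troughs < pk]
            if len(prior):
                last_amps.append(traj.cyclin_b[half:][pk] - traj.cyclin_b[half:][prior[-1]])
        if last_amps and np.mean(last_amps) > amplitude_threshold:
            return "oscillatory"
    return "stable_low" if traj.cyclin_b[-1] < LOW_HIGH_SPLIT_NM else "stable_high"


def sweep_r(
    p: RateParams,
    r_values,
    t_end: float = 3000.0,
) -> pd.DataFrame:
    """Regime plus post-transient cycle features for each r.

    Returns a table with columns r, regime, n_fixed_points, period_min,
    amplitude_nM, baseline_nM (features NaN outside the oscillatory regime).
    """
    rows = []
    for r in r_values:
        pr = p.with_(r=float(r))
        regime = classify_regime(pr, t_end=t_end)
        fps = find_fixed_points(pr)
        period = amplitude = baseline = np.nan
        if regime == "oscillatory":
            traj = simulate_deterministic(pr, (0.0, 0.0), t_end=t_end, dt_out=1.0)
            feats = trajectory_features(traj.times, traj.cyclin_b)
            period, amplitude, baseline = feats["period"], feats["amplitude"], feats["baseline"]
        rows.append(
            {
                "r": float(r),
                "regime": regime,
                "n_fixed_points": len(fps),
                "period_min": period,
                "amplitude_nM": amplitude,
                "baseline_nM": baseline,
            }
        )
    return pd.DataFrame(rows)
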