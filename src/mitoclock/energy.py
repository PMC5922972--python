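"""ATP-coupled oscillator: energy-dependent rates, the R ratio, depletion.

Wee1 and Cdc25 cycle between active and inactive forms through
phosphorylation reactions that consume ATP.  Assuming those reactions are
fast, the active fraction of each enzyme equilibrates at a value set by the
normalised ATP fraction A = [ATP]/([ATP]+[ADP]): Wee1 (active when
dephosphorylated) becomes more active as ATP falls, Cdc25 (active when
phosphorylated) less.  Calibrating the phosphorylation/dephosphorylation
rate-constant ratio so that the active fraction at A = 1/2 equals the
ATP-free steady state w0 (Wee1) or c0 (Cdc25) gives the closed forms

    wee1 active fraction  = w0·(1-A) / (A·(1-2·w0) + w0)
    cdc25 active fraction = c0·A / ((1-c0) + (2·c0-1)·A)

so the ATP-free reaction table is recovered exactly at A = 1/2.  The
Wee1:Cdc25 balance is summarised by the ratio R of the effective Wee1
inactivation rate coefficient to the effective Cdc25 activation rate
coefficient; R rises as ATP is depleted, sliding the oscillator toward the
high-cyclin arrested state and producing cycles of growing amplitude,
baseline and period on the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import _kernels
from .analysis import cycle_features, detect_peaks_troughs, trajectory_features
from .core_model import RateParams, hill_down, hill_up
from .stochastic import (
    CountState,
    StochasticRun,
    VolumeSpec,
    _params_vector,
    propensities,
    total_cyclin_series,
)

__all__ = [
    "EnergyParams",
    "EnergyState",
    "default_w0",
    "default_c0",
    "active_fraction_wee1",
    "active_fraction_cdc25",
    "propensities_energy",
    "balance_ratio_R",
    "gillespie_run_energy",
    "simulate_energy_depletion",
    "atp_R_curve",
    "cyclin_mrna_sweep",
]

#: default ATP stoichiometry per channel (rho1..rho5): the Wee1 and Cdc25
#: interconversion channels each consume one ATP
DEFAULT_ATP_COST = (0, 1, 1, 0, 0)

#: default depletion study conditions, sized (see docs) so the ATP fraction
#: traverses the oscillatory window (A roughly 0.6 down to 0.4 at r = 1)
#: over six to ten cycles at the default system size omega = 50
DEFAULT_ATP_FRAC0 = 0.65
DEFAULT_POOL = 2_500_000


def default_w0(cdk1a_conc, p: RateParams):
    """ATP-free steady-state active-Wee1 fraction: normalised repressive Hill."""
    return hill_down(cdk1a_conc, p.a_wee1, p.b_wee1, p.n_wee1, p.ec50_wee1) / (
        p.a_wee1 + p.b_wee1
    )


def default_c0(cdk1a_conc, p: RateParams):
    """ATP-free steady-state active-Cdc25 fraction: normalised activating Hill."""
    return hill_up(cdk1a_conc, p.a_cdc25, p.b_cdc25, p.n_cdc25, p.ec50_cdc25) / (
        p.a_cdc25 + p.b_cdc25
    )


@dataclass
class EnergyParams:
    """ATP pool, depletion mode and the enzyme active-fraction calibration.

    ``pool`` is the total ATP+ADP molecule count (conserved in
    stoichiometric mode); ``atp_cost`` gives the per-channel ATP
    stoichiometry.  ``w0_fun``/``c0_fun`` map an active-Cdk1 concentration
    (nM) to the ATP-free active fraction; the defaults reuse the model's own
    normalised Hill laws and are injectable.
    """

    atp_frac0: float = DEFAULT_ATP_FRAC0
    pool: int = DEFAULT_POOL
    depletion_mode: str = "none"  # none | stoichiometric | scheduled
    schedule: tuple[np.ndarray, np.ndarray] | None = None  # (times, A values)
    atp_cost: tuple[int, ...] = DEFAULT_ATP_COST
    w0_fun: Callable | None = None
    c0_fun: Callable | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.atp_frac0 <= 1.0):
            raise ValueError("atp_frac0 must be in [0, 1]")
        if self.depletion_mode not in ("none", "stoichiometric", "scheduled"):
            raise ValueError(f"unknown depletion_mode {self.depletion_mode!r}")
        if self.depletion_mode == "stoichiometric" and self.pool <= 0:
            raise ValueError("pool must be > 0 in stoichiometric mode")
        if self.depletion_mode == "scheduled" and self.schedule is None:
            raise ValueError("scheduled mode requires a schedule")
        if len(self.atp_cost) != 5 or any(c < 0 for c in self.atp_cost):
            raise ValueError("atp_cost must be five nonnegative integers")

    def w0(self, cdk1a_conc, p: RateParams):
        fun = self.w0_fun if self.w0_fun is not None else default_w0
        return fun(cdk1a_conc, p)

    def c0(self, cdk1a_conc, p: RateParams):
        fun = self.c0_fun if self.c0_fun is not None else default_c0
        return fun(cdk1a_conc, p)


@dataclass(frozen=True)
class EnergyState:
    """Count state extended with ATP/ADP molecule counts."""

    n_cdk1a: int
    n_cdk1i: int
    n_atp: int
    n_adp: int

    def __post_init__(self) -> None:
        if min(self.n_cdk1a, self.n_cdk1i, self.n_atp, self.n_adp) < 0:
            raise ValueError("all counts must be >= 0")

    @property
    def atp_frac(self) -> float:
        return self.n_atp / (self.n_atp + self.n_adp)


def active_fraction_wee1(atp_frac: float, w0: float) -> float:
    """Equilibrium active-Wee1 fraction at ATP fraction A.

    Monotone nonincreasing in A; equals w0 at A = 1/2, 1 at A = 0 and 0 at
    A = 1 (fully phosphorylated, inactive).
    """
    if not (0.0 <= atp_frac <= 1.0):
        raise ValueError("atp_frac must be in [0, 1]")
    if atp_frac == 0.5:
        return float(w0)
    denom = atp_frac * (1.0 - 2.0 * w0) + w0
    if denom <= 0:
        raise ValueError("invalid w0/A combination")
    return float(w0 * (1.0 - atp_frac) / denom)


def active_fraction_cdc25(atp_frac: float, c0: float) -> float:
    """Equilibrium active-Cdc25 fraction at ATP fraction A.

    Monotone nondecreasing in A; equals c0 at A = 1/2, 0 at A = 0 and 1 at
    A = 1 (fully phosphorylated, active).
    """
    if not (0.0 <= atp_frac <= 1.0):
        raise ValueError("atp_frac must be in [0, 1]")
    if atp_frac == 0.5:
        return float(c0)
    denom = (1.0 - c0) + (2.0 * c0 - 1.0) * atp_frac
    if denom <= 0:
        raise ValueError("invalid c0/A combination")
    return float(c0 * atp_frac / denom)


def _multipliers(conc: float, atp_frac: float, p: RateParams, e: EnergyParams) -> tuple[float, float]:
    """Channel multipliers (active fraction / reference fraction) for ρ2, ρ3."""
    if atp_frac == 0.5:
        return 1.0, 1.0
    w0 = float(e.w0(conc, p))
    c0 = float(e.c0(conc, p))
    return (
        active_fraction_wee1(atp_frac, w0) / w0,
        active_fraction_cdc25(atp_frac, c0) / c0,
    )


def propensities_energy(
    s: CountState | EnergyState,
    p: RateParams,
    e: EnergyParams,
    v: VolumeSpec,
    atp_frac: float | None = None,
) -> np.ndarray:
    """The five ATP-coupled channel propensities (1/min).

    Synthesis and the two degradation channels are unchanged; the Wee1 and
    Cdc25 interconversion channels are scaled by the ratio of the current
    active fraction to its A = 1/2 reference, so at A = 1/2 all five equal
    the plain table exactly.
    """
    if atp_frac is None:
        atp_frac = s.atp_frac if isinstance(s, EnergyState) else e.atp_frac0
    if not (0.0 <= atp_frac <= 1.0):
        raise ValueError("atp_frac must be in [0, 1]")
    base = propensities(CountState(s.n_cdk1a, s.n_cdk1i), p, v)
    m2, m3 = _multipliers(s.n_cdk1a / v.omega, atp_frac, p, e)
    out = base.copy()
    out[1] *= m2
    out[2] *= m3
    return out


def balance_ratio_R(
    s: CountState | EnergyState | float,
    p: RateParams,
    e: EnergyParams,
    v: VolumeSpec | None = None,
    atp_frac: float | None = None,
):
    """Wee1:Cdc25 balance ratio R at a state and ATP fraction.

    R is the effective Wee1 inactivation rate coefficient divided by the
    effective Cdc25 activation rate coefficient (per-molecule rates, i.e.
    ρ2/<Cdk1a> over ρ3/<Cdk1i>), so it is defined from rate coefficients
    even when either count is zero.  ``s`` may be a count state (with ``v``)
    or directly an active-Cdk1 concentration in nM.
    """
    if isinstance(s, (CountState, EnergyState)):
        if v is None:
            raise ValueError("v is required with a count state")
        conc = s.n_cdk1a / v.omega
        if atp_frac is None and isinstance(s, EnergyState):
            atp_frac = s.atp_frac
    else:
        conc = float(s)
    if atp_frac is None:
        atp_frac = e.atp_frac0
    hw = hill_down(conc, p.a_wee1, p.b_wee1, p.n_wee1, p.ec50_wee1)
    hc = hill_up(conc, p.a_cdc25, p.b_cdc25, p.n_cdc25, p.ec50_cdc25)
    m2, m3 = _multipliers(conc, atp_frac, p, e)
    return p.r * (hw * m2) / (hc * m3)


def _run_energy_kernel(p, v, init, t_end, seed, record_dt, mode, e, max_events):
    if isinstance(init, (CountState, EnergyState)):
        n_a0, n_i0 = init.n_cdk1a, init.n_cdk1i
    else:
        n_a0, n_i0 = init
    if mode == 3:
        sched_t, sched_a = e.schedule
        sched_t = np.asarray(sched_t, dtype=float)
        sched_a = np.asarray(sched_a, dtype=float)
    else:
        sched_t, sched_a = np.zeros(1), np.full(1, e.atp_frac0)
    times, n_a, n_i, counts, atp, status = _kernels.ssa_kernel(
        _params_vector(p),
        float(v.omega),
        np.int64(n_a0),
        np.int64(n_i0),
        float(t_end),
        float(record_dt),
        np.int64(seed),
        np.int64(mode),
        float(e.atp_frac0),
        np.int64(max(e.pool, 1)),
        np.asarray(e.atp_cost, dtype=np.int64),
        sched_t,
        sched_a,
        np.int64(max_events),
    )
    if status == _kernels.STATUS_MAX_EVENTS:
        raise RuntimeError(f"SSA exceeded max_events={max_events} before t_end")
    return StochasticRun(
        seed=seed,
        times=times,
        n_cdk1a=n_a,
        n_cdk1i=n_i,
        firing_counts=counts,
        atp_frac=atp,
        metadata={
            "params": p.to_dict(),
            "omega": v.omega,
            "seed": seed,
            "model": "energy",
            "energy_mode": mode,
            "atp_frac0": e.atp_frac0,
            "pool": e.pool,
        },
    )


def gillespie_run_energy(
    p: RateParams,
    v: VolumeSpec,
    e: EnergyParams,
    init: CountState | tuple[int, int] = (0, 0),
    t_end: float = 1000.0,
    seed: int = 0,
    record_dt: float = 1.0,
    max_events: int = 2_000_000_000,
) -> StochasticRun:
    """SSA over the ATP-coupled table with A held fixed at e.atp_frac0."""
    return _run_energy_kernel(p, v, init, t_end, seed, record_dt, 1, e, max_events)


def simulate_energy_depletion(
    p: RateParams,
    e: EnergyParams,
    v: VolumeSpec,
    init: CountState | tuple[int, int] = (0, 0),
    t_end: float = 3000.0,
    seed: int = 0,
    record_dt: float = 1.0,
    max_events: int = 2_000_000_000,
) -> StochasticRun:
    """SSA with ATP depletion: stoichiometric pool conversion or a schedule.

    In stoichiometric mode each firing of channel k converts atp_cost[k]
    ATP to ADP; A(t) = n_ATP/pool is recorded alongside the counts and the
    interconversion channels are gated off once the pool is exhausted.
    """
    if e.depletion_mode == "none":
        raise ValueError("depletion_mode must be stoichiometric or scheduled")
    mode = 2 if e.depletion_mode == "stoichiometric" else 3
    return _run_energy_kernel(p, v, init, t_end, seed, record_dt, mode, e, max_events)


def time_averaged_R(run: StochasticRun, p: RateParams, e: EnergyParams, v: VolumeSpec,
                    discard_frac: float = 0.25) -> float:
    """Post-transient time average of R along a recorded sample path."""
    start = int(len(run.times) * discard_frac)
    conc = run.n_cdk1a[start:] / v.omega
    atp = run.atp_frac[start:] if run.atp_frac is not None else np.full(len(conc), 0.5)
    vals = [balance_ratio_R(c, p, e, atp_frac=a) for c, a in zip(conc, atp)]
    return float(np.mean(vals))


def atp_R_curve(
    p: RateParams,
    e: EnergyParams,
    v: VolumeSpec,
    atp_fracs,
    n_reps: int = 3,
    seed: int = 0,
    t_end: float = 1000.0,
) -> pd.DataFrame:
    """Mean and range of the time-averaged R at each fixed ATP fraction.

    Runs ``n_reps`` seeded replicates per A (three by default, matching the
    replicate protocol of the simulated R-vs-ATP relationship).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, A in enumerate(atp_fracs):
        eA = EnergyParams(
            atp_frac0=float(A), pool=e.pool, depletion_mode="none",
            atp_cost=e.atp_cost, w0_fun=e.w0_fun, c0_fun=e.c0_fun,
        )
        child = np.random.SeedSequence(seed + 1000 * i)
        rvals = []
        for j in range(n_reps):
            s = int(child.generate_state(j + 1)[-1] % (2**31))
            run = gillespie_run_energy(p, v, eA, (0, 0), t_end=t_end, seed=s)
            rvals.append(time_averaged_R(run, p, eA, v))
        rows.append(
            {
                "atp_frac": float(A),
                "R_mean": float(np.mean(rvals)),
                "R_min": float(np.min(rvals)),
                "R_max": float(np.max(rvals)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def depletion_cycle_table(run: StochasticRun) -> pd.DataFrame:
    """Per-cycle period/amplitude/baseline sequences from a depletion run."""
    tot = total_cyclin_series(run).astype(float)
    feats = cycle_features(run.times, tot, droplet_id=run.seed)
    n = min(len(feats.periods), len(feats.amplitudes))
    return pd.DataFrame(
        {
            "cycle_index": np.arange(n),
            "period_min": feats.periods[:n],
            "amplitude": feats.amplitudes[:n],
            "baseline": feats.baselines[:n],
        }
    )


def cyclin_mrna_sweep(
    p: RateParams,
    e: EnergyParams,
    v: VolumeSpec,
    ksy_values,
    n_reps: int = 50,
    seed: int = 0,
    t_end: float = 3000.0,
) -> pd.DataFrame:
    """Period and completed-cycle statistics vs synthesis rate under depletion.

    For each ksy (a proxy for the cyclin B mRNA concentration) the
    stochastic depletion model is run ``n_reps`` times; the table reports
    mean ± SD of the per-run mean period and of the number of cycles
    completed before oscillations arrest.
    """
    if e.depletion_mode == "none":
        raise ValueError("cyclin sweep is defined under energy depletion")
    rows = []
    for i, ksy in enumerate(ksy_values):
        pk = p.with_(ksy=float(ksy))
        child = np.random.SeedSequence(seed + 7919 * i)
        periods, cycles = [], []
        for j in range(n_reps):
            s = int(child.generate_state(j + 1)[-1] % (2**31))
            run = simulate_energy_depletion(pk, e, v, (0, 0), t_end=t_end, seed=s)
            tot = total_cyclin_series(run).astype(float)
            feats = cycle_features(run.times, tot)
            cycles.append(feats.n_cycles)
            if len(feats.periods):
                periods.append(float(np.mean(feats.periods)))
        rows.append(
            {
                "ksy": float(ksy),
                "mean_period_min": float(np.mean(periods)) if periods else np.nan,
                "sd_period_min": float(np.std(periods)) if periods else np.nan,
                "mean_n_cycles": float(np.mean(cycles)),
                "sd_n_cycles": float(np.std(cycles)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
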