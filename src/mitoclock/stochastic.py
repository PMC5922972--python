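"""Droplet-scale exact stochastic simulation of the oscillator.

The two-ODE model maps onto five reaction channels over integer molecule
counts of active (<Cdk1a>) and inactive (<Cdk1i>) cyclin B–Cdk1 complex:

====  ================================  =========================
 ρ1   synthesis, ksy·Ω                  <Cdk1a> += 1
 ρ2   Wee1 inactivation                 <Cdk1a> -= 1, <Cdk1i> += 1
 ρ3   Cdc25 re-activation               <Cdk1i> -= 1, <Cdk1a> += 1
 ρ4   degradation of active complex     <Cdk1a> -= 1
 ρ5   degradation of inactive complex   <Cdk1i> -= 1
====  ================================  =========================

Rate-law arguments are concentrations <Cdk1a>/Ω so the EC50s keep their nM
meaning; Ω (molecules per nM) encodes the droplet volume.  Sample paths are
drawn with the direct-method Gillespie algorithm, statistically exact for
this jump process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from . import _kernels
from .core_model import RateParams, cdc25_rate, degradation_rate, wee1_rate

__all__ = [
    "VolumeSpec",
    "CountState",
    "StochasticRun",
    "counts_from_concentration",
    "propensities",
    "gillespie_run",
    "total_cyclin_series",
    "write_run",
]

#: molecules per nM per liter
_NM_PER_LITER = Avogadro * 1e-9


@dataclass(frozen=True)
class VolumeSpec:
    """Reaction volume and the derived system size Ω (molecules per nM)."""

    volume: float  # liters

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be > 0")

    @property
    def omega(self) -> float:
        return self.volume * _NM_PER_LITER

    @classmethod
    def from_omega(cls, omega: float) -> "VolumeSpec":
        if omega <= 0:
            raise ValueError("omega must be > 0")
        return cls(volume=omega / _NM_PER_LITER)


@dataclass(frozen=True)
class CountState:
    """Integer molecule counts of active and inactive complex."""

    n_cdk1a: int
    n_cdk1i: int

    def __post_init__(self) -> None:
        if self.n_cdk1a < 0 or self.n_cdk1i < 0:
            raise ValueError("molecule counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_cdk1a + self.n_cdk1i


@dataclass
class StochasticRun:
    """A recorded SSA sample path on a uniform grid (zero-order hold)."""

    seed: int
    times: np.ndarray
    n_cdk1a: np.ndarray
    n_cdk1i: np.ndarray
    firing_counts: np.ndarray  # (n_rec, 5) cumulative per channel
    atp_frac: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def counts_from_concentration(
    conc: float,
    v: VolumeSpec,
    mode: str = "round",
    seed: int | None = None,
) -> int:
    """Convert a concentration (nM) to an integer molecule count.

    ``round`` takes the nearest integer of conc·Ω; ``poisson`` draws from a
    Poisson with that mean (partition noise at encapsulation).
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    mean = conc * v.omega
    if mode == "round":
        return int(np.rint(mean))
    if mode == "poisson":
        rng = np.random.default_rng(seed)
        return int(rng.poisson(mean))
    raise ValueError(f"unknown mode {mode!r}")


def propensities(s: CountState, p: RateParams, v: VolumeSpec) -> np.ndarray:
    """The five channel propensities (1/min) at a count state.

    Hill arguments use the active-complex concentration n_cdk1a/Ω.
    """
    if s.n_cdk1a < 0 or s.n_cdk1i < 0:
        raise ValueError("negative molecule counts")
    conc = s.n_cdk1a / v.omega
    kdeg = degradation_rate(conc, p)
    return np.array(
        [
            p.ksy * v.omega,
            wee1_rate(conc, p) * s.n_cdk1a,
            cdc25_rate(conc, p) * s.n_cdk1i,
            kdeg * s.n_cdk1a,
            kdeg * s.n_cdk1i,
        ]
    )


def _params_vector(p: RateParams) -> np.ndarray:
    return np.array(
        [
            p.ksy,
            p.a_deg,
            p.b_deg,
            p.n_deg,
            p.ec50_deg,
            p.a_wee1,
            p.b_wee1,
            p.n_wee1,
            p.ec50_wee1,
            p.a_cdc25,
            p.b_cdc25,
            p.n_cdc25,
            p.ec50_cdc25,
            p.r,
        ]
    )


_DUMMY_SCHED = (np.zeros(1), np.full(1, 0.5))
_DUMMY_COST = np.zeros(5, dtype=np.int64)


def gillespie_run(
    p: RateParams,
    v: VolumeSpec,
    init: CountState | tuple[int, int] = (0, 0),
    t_end: float = 1000.0,
    seed: int = 0,
    record_dt: float = 1.0,
    max_events: int = 2_000_000_000,
) -> StochasticRun:
    """Exact SSA sample path of the five-channel system.

    The same seed yields a bit-identical run.  With all propensities zero
    (e.g. ksy = 0 from an empty state) the run terminates cleanly at the
    absorbing state and the grid is filled by holding it.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if isinstance(init, CountState):
        n_a0, n_i0 = init.n_cdk1a, init.n_cdk1i
    else:
        n_a0, n_i0 = init
    times, n_a, n_i, counts, _, status = _kernels.ssa_kernel(
        _params_vector(p),
        float(v.omega),
        np.int64(n_a0),
        np.int64(n_i0),
        float(t_end),
        float(record_dt),
        np.int64(seed),
        np.int64(0),  # energy_mode: none
        0.5,
        np.int64(1),
        _DUMMY_COST,
        _DUMMY_SCHED[0],
        _DUMMY_SCHED[1],
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
        atp_frac=None,
        metadata={"params": p.to_dict(), "omega": v.omega, "seed": seed, "model": "table1"},
    )


def total_cyclin_series(run: StochasticRun) -> np.ndarray:
    """Total cyclin B molecules (active + inactive) at each recorded time."""
    return run.n_cdk1a + run.n_cdk1i


def write_run(run: StochasticRun, path: str | Path) -> None:
    """CSV output with a JSON sidecar carrying seed, omega and parameters."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_min": run.times,
            "n_cdk1a": run.n_cdk1a,
            "n_cdk1i": run.n_cdk1i,
            "total_cyclin": total_cyclin_series(run),
        }
    )
    if run.atp_frac is not None:
        df["atp_frac"] = run.atp_frac
    df.to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(run.metadata, indent=2, default=str)
    )
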