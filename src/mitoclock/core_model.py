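"""Deterministic two-ODE model of the embryonic cell-cycle oscillator.

The model tracks total cyclin B1 concentration and the concentration of the
active cyclin B1–Cdk1 complex (Cdk1a), both in nM.  Cyclin B is synthesised at
a constant rate ``ksy`` and degraded by APC/C with a rate that switches on
sharply with Cdk1 activity (Hill exponent 17).  Newly made cyclin binds excess
Cdk1 and is immediately activated; the active complex is inactivated by the
kinase Wee1 (itself inhibited by Cdk1 — a double-negative loop) and
re-activated by the phosphatase Cdc25 (activated by Cdk1 — a positive loop).

The dimensionless parameter ``r`` is the ratio of the double-negative
(Wee1) to the positive (Cdc25) feedback strength: the Wee1 branch is scaled
by ``sqrt(r)`` and the Cdc25 branch by ``1/sqrt(r)``, so their ratio changes
by exactly ``r`` while the geometric-mean drive is preserved.  Sweeping
``r`` moves the system between a low stable steady state of cyclin B
(Cdc25-dominated), a limit-cycle regime, and a high stable steady state
(Wee1-dominated); with the default parameters the window containing
sustained oscillations includes r = 0.8 and r = 1.5, while r = 0.5 and
r = 2.5 sit in the low and high stable regimes respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "RateParams",
    "ConcState",
    "Trajectory",
    "hill_up",
    "hill_down",
    "degradation_rate",
    "wee1_rate",
    "cdc25_rate",
    "odes_rhs",
    "simulate_deterministic",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the two-ODE oscillator.

    The ``a_*``/``b_*`` coefficients for Wee1 and Cdc25 are first-order rate
    constants (1/min) multiplying a complex concentration; ``ksy`` is a
    zero-order synthesis rate in nM/min.  EC50s are in nM, Hill exponents
    dimensionless.  ``r`` is the Wee1:Cdc25 feedback-strength ratio; it
    enters the rate laws as ``sqrt(r)`` on the Wee1 branch and
    ``1/sqrt(r)`` on the Cdc25 branch.
    """

    ksy: float = 1.0
    a_deg: float = 0.01
    b_deg: float = 0.04
    n_deg: float = 17.0
    ec50_deg: float = 32.0
    a_wee1: float = 0.08
    b_wee1: float = 0.4
    n_wee1: float = 3.5
    ec50_wee1: float = 35.0
    a_cdc25: float = 0.16
    b_cdc25: float = 0.8
    n_cdc25: float = 11.0
    ec50_cdc25: float = 30.0
    r: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ksy", "a_deg", "b_deg", "a_wee1", "b_wee1", "a_cdc25", "b_cdc25"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_deg", "n_wee1", "n_cdc25", "ec50_deg", "ec50_wee1", "ec50_cdc25", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def with_(self, **kwargs) -> "RateParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ConcState:
    """Concentrations (nM) of total cyclin B1 and active cyclin B1–Cdk1."""

    cyclin_b: float
    cdk1a: float

    def __post_init__(self) -> None:
        if self.cyclin_b < 0:
            raise ValueError(f"cyclin_b must be >= 0, got {self.cyclin_b}")
        if not (0.0 <= self.cdk1a <= self.cyclin_b):
            raise ValueError(
                f"cdk1a must satisfy 0 <= cdk1a <= cyclin_b, got "
                f"cdk1a={self.cdk1a}, cyclin_b={self.cyclin_b}"
            )

    @property
    def cdk1i(self) -> float:
        """Inactive-complex concentration, cyclin_b - cdk1a."""
        return self.cyclin_b - self.cdk1a


@dataclass
class Trajectory:
    """Time grid (min) plus aligned state series from either solver."""

    times: np.ndarray
    cyclin_b: np.ndarray
    cdk1a: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cyclin_b = np.asarray(self.cyclin_b, dtype=float)
        self.cdk1a = np.asarray(self.cdk1a, dtype=float)
        if not (len(self.times) == len(self.cyclin_b) == len(self.cdk1a)):
            raise ValueError("times and state series must have equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times[0] must be >= 0")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def hill_up(x: float, a: float, b: float, n: float, ec50: float) -> float:
    """Activating Hill rate law ``a + b*x^n / (x^n + ec50^n)``.

    Bounded in [a, a+b] and monotone nondecreasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if ec50 <= 0 or n <= 0:
        raise ValueError("ec50 and n must be > 0")
    # (x/ec50)^n form avoids overflow for large x with big exponents
    q = (x / ec50) ** n
    out = a + b * q / (q + 1.0)
    return float(out) if out.ndim == 0 else out


def hill_down(x: float, a: float, b: float, n: float, ec50: float) -> float:
    """Repressive Hill rate law ``a + b*ec50^n / (x^n + ec50^n)``.

    Equals ``a + b`` at ``x = 0`` and decays to the basal floor ``a``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if ec50 <= 0 or n <= 0:
        raise ValueError("ec50 and n must be > 0")
    q = (x / ec50) ** n
    out = a + b / (q + 1.0)
    return float(out) if out.ndim == 0 else out


def degradation_rate(cdk1a, p: RateParams):
    """APC/C-mediated cyclin degradation rate constant (1/min)."""
    return hill_up(cdk1a, p.a_deg, p.b_deg, p.n_deg, p.ec50_deg)


def wee1_rate(cdk1a, p: RateParams):
    """Effective Wee1 inactivation rate constant (1/min), scaled by sqrt(r)."""
    return np.sqrt(p.r) * hill_down(cdk1a, p.a_wee1, p.b_wee1, p.n_wee1, p.ec50_wee1)


def cdc25_rate(cdk1a, p: RateParams):
    """Effective Cdc25 re-activation rate constant (1/min), scaled by 1/sqrt(r)."""
    return (1.0 / np.sqrt(p.r)) * hill_up(cdk1a, p.a_cdc25, p.b_cdc25, p.n_cdc25, p.ec50_cdc25)


def odes_rhs(s: ConcState | tuple[float, float], p: RateParams) -> tuple[float, float]:
    """Time derivatives (nM/min) of (cyclin_b, cdk1a).

    d[CyclinB]/dt = ksy - kdeg(Cdk1a)*[CyclinB]
    d[Cdk1a]/dt   = ksy + kcdc25(Cdk1a)*([CyclinB]-[Cdk1a])
                        - kwee1(Cdk1a)*[Cdk1a] - kdeg(Cdk1a)*[Cdk1a]
    """
    if isinstance(s, ConcState):
        cyc, act = s.cyclin_b, s.cdk1a
    else:
        cyc, act = s
        if cyc < 0 or act < 0 or act > cyc:
            raise ValueError(f"state ({cyc}, {act}) violates 0 <= cdk1a <= cyclin_b")
    kdeg = degradation_rate(act, p)
    d_cyc = p.ksy - kdeg * cyc
    d_act = p.ksy + cdc25_rate(act, p) * (cyc - act) - wee1_rate(act, p) * act - kdeg * act
    return d_cyc, d_act


def _rhs_unchecked(t, y, p: RateParams):
    cyc, act = y
    act = max(act, 0.0)
    kdeg = degradation_rate(act, p)
    d_cyc = p.ksy - kdeg * cyc
    d_act = p.ksy + cdc25_rate(act, p) * (cyc - act) - wee1_rate(act, p) * act - kdeg * act
    return (d_cyc, d_act)


def simulate_deterministic(
    p: RateParams,
    init: ConcState | tuple[float, float] = (0.0, 0.0),
    t_end: float = 2000.0,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the two-ODE model with a stiff-capable solver.

    The n=17 degradation Hill function makes the system stiff near the
    mitotic trigger, so LSODA (automatic stiff/non-stiff switching) is used
    with tight tolerances.  Output is sampled on a uniform grid of spacing
    ``dt_out``; tiny negative excursions and ``cdk1a > cyclin_b`` roundoff
    violations are clipped at output only.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if isinstance(init, ConcState):
        y0 = (init.cyclin_b, init.cdk1a)
    else:
        y0 = tuple(init)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        _rhs_unchecked,
        (0.0, t_end),
        y0,
        args=(p,),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t={sol.t[-1] if len(sol.t) else 0.0} min: "
            f"{sol.message}"
        )
    cyc = np.clip(sol.y[0], 0.0, None)
    act = np.clip(sol.y[1], 0.0, cyc)
    return Trajectory(
        times=sol.t,
        cyclin_b=cyc,
        cdk1a=act,
        metadata={"params": p.to_dict(), "solver": "LSODA", "rtol": rtol, "atol": atol},
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with a JSON parameter sidecar.

    Full float precision (repr round-trip) so read/write is lossless.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_min": traj.times,
            "cyclin_b_nM": traj.cyclin_b,
            "cdk1a_nM": traj.cdk1a,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(traj.metadata, indent=2, default=str))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Trajectory(
        times=df["time_min"].to_numpy(),
        cyclin_b=df["cyclin_b_nM"].to_numpy(),
        cdk1a=df["cdk1a_nM"].to_numpy(),
        metadata=metadata,
    )
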