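"""Synthetic droplet populations with rendered fluorescence traces.

Emulates the statistical structure of water-in-oil droplet encapsulation
experiments: a log-normal droplet size distribution squashed inside a
chamber of fixed height, Poisson partitioning of reporter/cyclin mRNA
molecules by volume, a per-droplet stochastic oscillator run under energy
depletion, and linear rendering of total cyclin into a multi-channel
fluorescence time course with background drift and measurement noise.

Simulation scale.  True droplet volumes correspond to system sizes up to
~10^7 molecules/nM, far beyond what exact SSA populations can cover; each
droplet is therefore simulated at a volume-proportional reduced molecular
scale (``omega_scale`` with a floor and cap), applied consistently to both
mRNA partitioning and protein counts so partition noise and intrinsic
reaction noise retain their relative size dependence.  Direction-level
population trends are preserved; absolute copy numbers are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.constants import Avogadro

from .core_model import RateParams
from .energy import EnergyParams, simulate_energy_depletion
from .stochastic import StochasticRun, VolumeSpec, gillespie_run, total_cyclin_series

__all__ = [
    "DropletSpec",
    "FluorescenceTrace",
    "ExperimentConfig",
    "droplet_volume",
    "sample_droplet_population",
    "partition_mrna",
    "mrna_to_ksy",
    "render_trace",
    "generate_experiment",
    "write_trace_table",
    "read_trace_table",
]

#: g/mol per nucleotide of single-stranded mRNA
MRNA_G_PER_MOL_PER_NT = 330.0
#: default mRNA length (nt), full-length cyclin B1 fused to a YFP reporter
DEFAULT_MRNA_LENGTH_NT = 2000
#: synthesis-rate gain per nM of cyclin B mRNA (nM/min per nM); calibrated so
#: the 0-10 ng/uL condition grid spans ksy ~1.0-2.0, covering the oscillator's
#: sustained-oscillation range through to mitotic arrest
KSY_PER_NM_MRNA = 0.066
#: endogenous synthesis rate (nM/min) of the 0 ng/uL condition
KSY_ENDOGENOUS = 1.0
#: molecules per nM per liter
_NM_PER_LITER = Avogadro * 1e-9
#: ATP+ADP pool molecules per unit omega (depletion timescale invariant in size)
POOL_PER_OMEGA = 50_000.0


@dataclass
class DropletSpec:
    """Geometry, mRNA content and seed of one synthetic droplet."""

    droplet_id: int
    observed_diameter: float  # um
    chamber_height: float  # um
    volume: float  # liters
    equivalent_diameter: float  # um
    mrna_conc: dict  # condition -> ng/uL per reporter
    partitioned_mrna_counts: dict = field(default_factory=dict)
    seed: int = 0
    sim_omega: float = 0.0  # molecules per nM at simulation scale


@dataclass
class FluorescenceTrace:
    """Uniformly sampled multi-channel intensity time course (a.u.)."""

    times: np.ndarray  # min
    channels: dict  # name -> intensity array
    background: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise ValueError("times must be uniformly spaced")


def droplet_volume(observed_diameter: float, chamber_height: float = 100.0) -> tuple[float, float]:
    """Volume (liters) and equivalent diameter (um) of a chamber-squashed droplet.

    A droplet with observed (in-plane) diameter d below the chamber height h
    is an unconstrained sphere.  A larger droplet is modelled as a cylinder
    of height h and diameter d - h with a half-torus rim of tube radius h/2:
    V = pi*a^2*h + pi^2*h^2*a/4 + pi*h^3/6 with a = (d-h)/2, which reduces
    to the sphere volume exactly at d = h and is monotone in d.  The
    equivalent diameter is that of the sphere of equal volume, (6V/pi)^(1/3).
    """
    d, h = float(observed_diameter), float(chamber_height)
    if d <= 0 or h <= 0:
        raise ValueError("diameter and chamber height must be > 0")
    if d <= h:
        v_um3 = np.pi * d**3 / 6.0
    else:
        a = (d - h) / 2.0
        v_um3 = np.pi * a**2 * h + np.pi**2 * h**2 * a / 4.0 + np.pi * h**3 / 6.0
    volume_l = v_um3 * 1e-15
    eq_diam = (6.0 * v_um3 / np.pi) ** (1.0 / 3.0)
    return volume_l, eq_diam


def _child_seed(master_seed: int, *path: int) -> int:
    """Deterministic child seed derived from a master seed by fixed arithmetic."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, path)]).generate_state(1)[0] % (2**31))


def sample_droplet_population(
    n: int,
    mrna_conc: dict | None = None,
    master_seed: int = 0,
    median_diameter: float = 80.0,
    sigma_log: float = 0.5,
    chamber_height: float = 100.0,
    eq_diameter_range: tuple[float, float] = (20.0, 600.0),
) -> list[DropletSpec]:
    """Draw ``n`` droplet specs with log-normal observed diameters.

    The size law is a modelling choice (droplet vortexing produces broad,
    right-skewed size distributions); draws whose equivalent diameter falls
    outside ``eq_diameter_range`` are rejected and redrawn.  Child seeds
    derive deterministically from the master seed.
    """
    mrna_conc = dict(mrna_conc or {})
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 0xD0]))
    specs = []
    for i in range(n):
        for _ in range(1000):
            d = float(np.exp(rng.normal(np.log(median_diameter), sigma_log)))
            vol, eq = droplet_volume(d, chamber_height)
            if eq_diameter_range[0] <= eq <= eq_diameter_range[1]:
                break
        else:
            raise RuntimeError("size rejection sampling failed; check size law vs range")
        specs.append(
            DropletSpec(
                droplet_id=i,
                observed_diameter=d,
                chamber_height=chamber_height,
                volume=vol,
                equivalent_diameter=eq,
                mrna_conc=mrna_conc,
                seed=_child_seed(master_seed, 1, i),
            )
        )
    return specs


def mrna_molar_from_ng_per_ul(conc_ng_per_ul: float, length_nt: int = DEFAULT_MRNA_LENGTH_NT) -> float:
    """mRNA molar concentration (mol/L) from a mass concentration in ng/uL."""
    mw = MRNA_G_PER_MOL_PER_NT * length_nt  # g/mol
    return conc_ng_per_ul * 1e-3 / mw  # ng/uL == 1e-3 g/L


def partition_mrna(
    volume: float,
    conc_ng_per_ul: float,
    mrna_length_nt: int = DEFAULT_MRNA_LENGTH_NT,
    seed: int = 0,
) -> int:
    """Poisson-partitioned mRNA copy number in a droplet of given volume (L)."""
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be >= 0")
    lam = mrna_molar_from_ng_per_ul(conc_ng_per_ul, mrna_length_nt) * Avogadro * volume
    rng = np.random.default_rng(seed)
    return int(rng.poisson(lam))


def mrna_to_ksy(
    copies: int,
    volume: float,
    kappa: float = KSY_PER_NM_MRNA,
    ksy_endogenous: float = KSY_ENDOGENOUS,
) -> float:
    """Cyclin B synthesis rate (nM/min) from partitioned mRNA copies.

    Linear in the realised mRNA concentration: ksy = ksy_endogenous +
    kappa * (copies / volume in nM).  Zero copies give the endogenous rate
    exactly.
    """
    conc_nm = copies / (volume * _NM_PER_LITER)
    return float(ksy_endogenous + kappa * conc_nm)


def render_trace(
    run: StochasticRun,
    spec: DropletSpec,
    frame_interval: float = 7.5,
    gains: dict | None = None,
    background_level: float = 100.0,
    drift_per_min: float = 0.1 / 1440.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FluorescenceTrace:
    """Render a model run as a multi-channel fluorescence trace.

    Channel intensity is gain x total cyclin (resampled to the frame grid)
    times a shared multiplicative background drift, plus additive Gaussian
    noise, floored at zero.  The background channel carries the same drift
    so ratio normalisation removes it.  Default drift is 10% per day.
    """
    gains = gains or {"cyclinB1-YFP": 1.0, "securin-mCherry": 0.8}
    tot = total_cyclin_series(run).astype(float)
    frames = np.arange(0.0, run.times[-1] + 1e-9, frame_interval)
    sig = np.interp(frames, run.times, tot)
    drift = 1.0 + drift_per_min * frames
    rng = np.random.default_rng(seed)
    channels = {}
    for name, gain in gains.items():
        noisy = gain * sig * drift
        if noise_sd > 0:
            noisy = noisy + rng.normal(0.0, noise_sd, size=len(frames))
        channels[name] = np.clip(noisy, 0.0, None)
    bg = background_level * drift
    if noise_sd > 0:
        bg = np.clip(bg + rng.normal(0.0, 0.1 * noise_sd, size=len(frames)), 1e-6, None)
    return FluorescenceTrace(times=frames, channels=channels, background=bg)


@dataclass
class ExperimentConfig:
    """Configuration of a full synthetic droplet experiment."""

    master_seed: int
    conditions: tuple[float, ...] = (0.0, 3.0, 5.0, 8.0, 10.0)  # cyclin B mRNA ng/uL
    n_per_condition: int = 60
    t_end: float = 2500.0
    frame_interval: float = 7.5
    r: float = 1.0
    median_diameter: float = 80.0
    sigma_log: float = 0.5
    chamber_height: float = 100.0
    omega_scale: float = 0.01
    omega_min: float = 25.0
    omega_max: float = 500.0
    pool_per_omega: float = POOL_PER_OMEGA
    atp_frac0: float = 0.65
    depletion: bool = True  # False: plain oscillator (isolates size noise)
    noise_sd: float = 0.0
    mrna_length_nt: int = DEFAULT_MRNA_LENGTH_NT
    kappa: float = KSY_PER_NM_MRNA

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "master_seed" not in data:
            raise ValueError("config must set master_seed")
        data["conditions"] = tuple(data.get("conditions", (0.0, 3.0, 5.0, 8.0, 10.0)))
        return cls(**data)


def _sim_omega(volume_l: float, cfg: ExperimentConfig) -> float:
    true_omega = volume_l * _NM_PER_LITER
    return float(np.clip(true_omega * cfg.omega_scale, cfg.omega_min, cfg.omega_max))


def generate_experiment(
    config: ExperimentConfig,
    master_seed: int | None = None,
    params: RateParams | None = None,
) -> list[tuple[DropletSpec, FluorescenceTrace]]:
    """Run a full synthetic experiment across mRNA conditions.

    For each condition and droplet: sample geometry, Poisson-partition the
    cyclin B mRNA at the droplet's simulation scale, map copies to a
    synthesis rate, run the stochastic oscillator under stoichiometric ATP
    depletion, and render the fluorescence trace.  Fully deterministic
    under the master seed.
    """
    seed = config.master_seed if master_seed is None else master_seed
    base = params or RateParams(r=config.r)
    out = []
    uid = 0
    for ci, conc in enumerate(config.conditions):
        specs = sample_droplet_population(
            config.n_per_condition,
            mrna_conc={"cyclinB1-YFP": float(conc)},
            master_seed=_child_seed(seed, 10, ci),
            median_diameter=config.median_diameter,
            sigma_log=config.sigma_log,
            chamber_height=config.chamber_height,
        )
        for spec in specs:
            spec.droplet_id = uid
            omega = _sim_omega(spec.volume, config)
            spec.sim_omega = omega
            sim_volume = omega / _NM_PER_LITER
            copies = partition_mrna(
                sim_volume, conc, config.mrna_length_nt, seed=_child_seed(seed, 20, uid)
            )
            spec.partitioned_mrna_counts = {"cyclinB1-YFP": copies}
            ksy = mrna_to_ksy(copies, sim_volume, kappa=config.kappa)
            p = base.with_(ksy=ksy)
            run_seed = _child_seed(seed, 30, uid)
            record_dt = max(1.0, config.frame_interval / 4.0)
            if config.depletion:
                e = EnergyParams(
                    atp_frac0=config.atp_frac0,
                    pool=int(config.pool_per_omega * omega),
                    depletion_mode="stoichiometric",
                )
                run = simulate_energy_depletion(
                    p, e, VolumeSpec.from_omega(omega), (0, 0),
                    t_end=config.t_end, seed=run_seed, record_dt=record_dt,
                )
            else:
                run = gillespie_run(
                    p, VolumeSpec.from_omega(omega), (0, 0),
                    t_end=config.t_end, seed=run_seed, record_dt=record_dt,
                )
            trace = render_trace(
                run, spec,
                frame_interval=config.frame_interval,
                noise_sd=config.noise_sd,
                seed=_child_seed(seed, 40, uid),
            )
            out.append((spec, trace))
            uid += 1
    return out


def write_trace_table(experiment, path: str | Path, condition_key: str = "cyclinB1-YFP") -> None:
    """Write an experiment as a long-format trace table CSV."""
    rows = []
    for spec, trace in experiment:
        cond = spec.mrna_conc.get(condition_key, 0.0)
        for name, ch in trace.channels.items():
            for t, y, b in zip(trace.times, ch, trace.background):
                rows.append(
                    (spec.droplet_id, cond, t, name, y, b,
                     spec.observed_diameter, spec.equivalent_diameter)
                )
    pd.DataFrame(
        rows,
        columns=[
            "droplet_id", "condition", "time_min", "channel", "intensity",
            "background", "observed_diameter_um", "equivalent_diameter_um",
        ],
    ).to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format trace table CSV."""
    return pd.read_csv(path)
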