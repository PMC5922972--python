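# Methods

## The oscillator model

The core model is a two-variable relaxation oscillator for the embryonic
cell cycle: total cyclin B1 (`[CycB]`, nM) and active cyclin B1–Cdk1
complex (`[Cdk1a]`, nM).  Cyclin is synthesised at a constant rate
`k_sy = 1 nM/min`; every newly made molecule binds excess Cdk1 and is
immediately activated (Cdk1 is assumed non-limiting and cyclin–Cdk1
affinity high, so no free cyclin pool is tracked).  Three Hill-type rate
laws close the feedback loops:

| law | form | a (1/min) | b (1/min) | n | EC50 (nM) |
|---|---|---|---|---|---|
| degradation `k_deg` | activating | 0.01 | 0.04 | 17 | 32 |
| Wee1 `k_wee1` | repressive | 0.08 | 0.4 | 3.5 | 35 |
| Cdc25 `k_cdc25` | activating | 0.16 | 0.8 | 11 | 30 |

The `a_*`/`b_*` coefficients multiply a complex concentration in the rate
equations, so they are treated as first-order rate constants (1/min)
throughout.  The inactive pool is `[Cdk1i] = [CycB] − [Cdk1a]`.

### The feedback-balance parameter r

`r` is defined as the ratio of the double-negative (Wee1) to the positive
(Cdc25) feedback strength.  It enters the rate laws symmetrically as
`√r · k_wee1` and `k_cdc25 / √r`, so the strength *ratio* changes by
exactly `r` while the geometric mean of the two branch strengths is
preserved.  This placement is a deliberate design choice: with the
parameters above it yields a low stable steady state at r = 0.5 (cyclin
≈ 39 nM), sustained limit cycles at r = 0.8 (period ≈ 59 min) and r = 1.5
(period ≈ 218 min, with larger amplitude and baseline), and a high stable
steady state at r = 2.5 (cyclin ≈ 100 nM = k_sy/a_deg) — one fixed point
in each case, unstable inside the oscillatory window.  Scaling both
branches linearly in r instead would move the strength ratio by r² and
compress the oscillatory window to roughly r ∈ (0.83, 1.25), which is
inconsistent with the regime structure above; the square-root placement is
the unique symmetric reading under which r *is* the strength ratio.

### Numerics

The n = 17 degradation switch makes the system stiff near the mitotic
trigger; integration uses LSODA with rtol 1e-8 / atol 1e-10 and a uniform
1-min output grid (separate from internal adaptive stepping).  Halving the
tolerances moves the post-transient period by well under 0.1%.  Roundoff
excursions (`cyclin_b` slightly negative, `cdk1a` marginally above
`cyclin_b`) are clipped at output only, never mid-integration.  The default
initial state is the origin (0, 0) nM.  For post-transient feature
statistics everything before the second detected peak is discarded.

## Phase-plane analysis

The cyclin nullcline is `B = k_sy / k_deg(c)` (r-independent); the Cdk1
nullcline is solved algebraically for `B`.  Fixed points are bracketed on a
dense grid of the nullcline gap over Cdk1a ∈ [0, 120] nM (the domain
encloses all EC50s; configurable) and refined by Brent's method
(deduplication 1e-4 nM); stability comes from the analytic Jacobian
(eigenvalue marginality tolerance 1e-6 1/min).  Regime classification
combines fixed-point stability with a 3000-min simulation from the origin:
a mean peak-to-trough amplitude above 1 nM over the last three cycles is
oscillatory; otherwise the attractor's cyclin level relative to 60 nM
(midway between the low and high steady states) separates `stable_low`
from `stable_high`.

## Stochastic simulation

The model maps onto five reaction channels over integer counts of active
and inactive complex.  Rate-law arguments are concentrations (counts/Ω), so
EC50s keep their nM meaning at any volume; Ω = volume × N_A × 1e-9 is the
system size in molecules/nM.  Sample paths use the direct-method Gillespie
algorithm (statistically exact), implemented as a numba kernel with
recording by zero-order hold on a uniform grid (default 1 min) plus
cumulative per-channel firing counts; the full event log is not stored.
One seeded RNG stream drives each run; population runs derive child seeds
from a master seed by fixed SeedSequence arithmetic.  Tau-leaping was
considered and rejected: the depletion runs used here are short enough that
exact simulation stays cheap.

Figure-style runs default to Ω = 50 molecules/nM (~83 fL, a ~54 µm
droplet), putting total cyclin B in the low thousands of molecules.  The
volume used in the original droplet-scale simulations is not recorded
anywhere; this default is the package's own documented choice.

## Energy (ATP) coupling

Wee1 and Cdc25 interconvert between active and inactive forms through
phosphorylation reactions that consume ATP.  Treating those reactions as
fast, the active fraction of each enzyme equilibrates at a value set by
A = [ATP]/([ATP]+[ADP]).  With the phosphorylation/dephosphorylation rate
constant ratio calibrated so the active fraction at A = 1/2 equals the
ATP-free steady-state fraction (w0 for Wee1, c0 for Cdc25):

    wee1 active fraction  = w0·(1−A) / (A·(1−2·w0) + w0)
    cdc25 active fraction = c0·A / ((1−c0) + (2·c0−1)·A)

The Wee1/Cdc25 channels are scaled by active-fraction / reference-fraction,
so at A = 1/2 the plain reaction table is recovered exactly (the identity
is special-cased to be bit-exact).  w0(c) and c0(c) default to the model's
own normalised Hill laws — the upstream source for enzyme-specific values
prints no parameters — and both are injectable.  The balance ratio
`R = (effective Wee1 coefficient)/(effective Cdc25 coefficient)` is
computed from rate coefficients, so it is defined even at zero counts;
R rises monotonically as A falls.

Depletion modes: `stoichiometric` (default interpretation) converts one ATP
to ADP per Wee1/Cdc25 interconversion firing out of a conserved pool, with
the interconversion channels gated off once ATP is exhausted; `scheduled`
follows a prescribed piecewise-constant A(t).  How ATP actually declined in
the original simulations is not recorded; both modes are labelled
interpretations.  ATP costs per channel are configurable (synthesis and
degradation costs default to zero).

### Study conditions

Chosen once from a fixed-A scan at r = 1, Ω = 50 (oscillatory window
A ≈ 0.62–0.38, interconversion flux ≈ 750 firings/min):

* depletion runs: A₀ = 0.65, pool = 2.5×10⁶ molecules — the ATP fraction
  traverses the window over ~6–10 cycles, each later cycle slower, larger
  and higher-based until arrest;
* R-versus-ATP curve: A ∈ {0.6, 0.55, 0.5, 0.45, 0.4}, inside the
  self-sustained-oscillation range, 3 replicates per point;
* cyclin-synthesis sweep: ksy ∈ {1.0, 1.25, 1.5, 1.75, 2.0} under default
  depletion, 50 replicates (10 in the shipped tests/acceptance script to
  keep runtimes short; the statistic is a mean ± SD either way).

A known limitation: under depletion the oscillation-onset threshold in R
rises with ksy, so higher-synthesis runs oscillate later, in a lower-A /
higher-R window where cycles are intrinsically slower (the same mechanism
that makes period increase with r).  The mean cycle count therefore falls
with ksy as expected, but the mean period *rises* — the model, under every
protocol variant we tried, does not jointly produce falling period and
falling cycle count along the synthesis axis.  The sweep reports what the
model computes.

## Synthetic droplet experiments

The generator emulates: a log-normal observed-diameter law (median 80 µm,
σ_log = 0.5 — the real size distribution is not recorded; droplet vortexing
gives broad right-skewed sizes), chamber squashing at height 100 µm with a
cylinder-plus-half-torus-rim volume for diameters above the chamber height
(continuous at d = h, monotone, bounded by inscribed/circumscribed solids),
equivalent diameter (6V/π)^(1/3) truncated to [20, 600] µm, Poisson
partitioning of cyclin B mRNA (330 g/mol/nt, default length 2000 nt), a
linear mRNA→synthesis map `ksy = 1 + κ·[mRNA in nM]` with κ = 0.066 so the
0–10 ng/µL condition grid spans ksy ≈ 1.0–2.0 (sustained oscillation
through mitotic arrest), a per-droplet stochastic run, and linear
fluorescence rendering: gain × total cyclin resampled to 7.5-min frames
(midpoint of the 6–9 min imaging interval), shared multiplicative
background drift (default 10%/day) plus optional additive Gaussian noise,
floored at zero, with a background channel for ratio normalisation.

True droplet volumes imply Ω up to ~10⁷ molecules/nM — intractable for
exact-SSA populations — so each droplet runs at a volume-proportional
reduced molecular scale (default 1% of true Ω, clipped to [25, 500]),
applied consistently to mRNA partitioning and protein counts.  Population
trends in *direction* are what the generator preserves; absolute copy
numbers and absolute variance magnitudes are not, and passing tests say
nothing about surface or boundary effects in real droplets, which are not
modelled.

The size-noise analysis uses a dedicated configuration
(`pipeline.size_noise_config`): endogenous condition only (mirroring the
pooled 0 ng/µL analysis), no depletion (so the period spread isolates
compartmentalisation stochasticity), a deeper scale reduction (Ω down to
single digits in the smallest droplets, cap 400) so period jitter resolves
above the 7.5-min frame interval, and a 600-min observation window (about
seven cycles) so per-droplet averaging does not erase the size gradient.
Under these conditions the 25th–75th percentile period band is several-fold
wider in the smallest size bin than the largest, robustly across master
seeds.

## Trace analysis

Intensities are divided pointwise by the background channel, cancelling
multiplicative drift.  Peaks and troughs come from prominence-based
detection (default prominence 10% of the global signal range, minimum
separation 3 frames) with alternation enforced by keeping the extremal
point between same-kind neighbours — a deterministic surrogate for manual
peak curation; the thresholds were calibrated on synthetic fixtures only.
Per-cycle features: period = successive peak-to-peak interval, amplitude =
peak minus preceding trough, baseline = trough value.  Tracks with fewer
than two oscillations are discarded.  Population summaries use medians with
unscaled MAD error bars (no 1.4826 consistency factor — none is used in the
reported statistic).  Size bands: droplets sorted by equivalent diameter,
running 25th/50th/75th percentiles over 50-droplet bins (linear
interpolation; a short remainder merges into the last bin; fewer than 50
droplets fall back to a single bin), edges smoothed by LOWESS over 20-point
windows.  Period drift is summarised per droplet by the Kendall tau of
period versus cycle index plus a pooled median period per cycle index.

## Determinism

Every stochastic entry point takes an explicit seed; population stages
derive child seeds from a master seed by fixed arithmetic (never from
time).  Recipes write a manifest with a sha256 hash of every output;
rerunning a recipe with the same configuration and seed reproduces the
files byte for byte.
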