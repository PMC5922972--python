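# mitoclock

Simulation and analysis toolkit for the cyclin B1–Cdk1 mitotic oscillator as
reconstituted in cell-free *Xenopus* egg extract droplets ("artificial
cells").  The package targets researchers studying clock tunability and
stochasticity in droplet microfluidic oscillator experiments: it provides
the deterministic two-ODE oscillator model, an exact Gillespie simulator of
its droplet-scale (finite molecule number) counterpart, an ATP/energy-
depletion extension that reproduces the slow drift and eventual arrest of
extract oscillations, a synthetic droplet-population generator, and the
trace-analysis pipeline (background normalisation, peak detection, per-cycle
features, population summaries) used to quantify such experiments.

## Model

Total cyclin B1 and active cyclin B1–Cdk1 (`Cdk1a`, both nM) evolve as

    d[CycB]/dt  = k_sy − k_deg(Cdk1a)·[CycB]
    d[Cdk1a]/dt = k_sy + k_cdc25(Cdk1a)·([CycB] − [Cdk1a])
                       − k_wee1(Cdk1a)·[Cdk1a] − k_deg(Cdk1a)·[Cdk1a]

with Hill-type rate laws: APC/C-mediated degradation
`k_deg = a_deg + b_deg·c^n/(c^n + K^n)` switches on sharply with Cdk1
activity (n = 17), Cdc25 re-activation rises with Cdk1 activity (n = 11,
positive feedback) and Wee1 inactivation falls with it (n = 3.5,
double-negative feedback).  A dimensionless parameter `r` — the ratio of
the double-negative to the positive feedback strength — scales the Wee1
branch by `√r` and the Cdc25 branch by `1/√r`.  Sweeping `r` moves the
system from a low stable steady state of cyclin B through a limit-cycle
window into a high stable steady state.

At droplet scale the same chemistry becomes five reaction channels over
integer molecule counts (synthesis, Wee1 inactivation, Cdc25 re-activation,
degradation of each pool), sampled exactly with the direct-method Gillespie
algorithm; the system size Ω (molecules per nM) encodes droplet volume.
The energy extension makes Wee1/Cdc25 phosphorylation ATP-dependent through
equilibrium active fractions parameterised by A = [ATP]/([ATP]+[ADP]); as a
finite ATP pool is consumed, the Wee1:Cdc25 balance ratio R rises and
cycles grow in amplitude, baseline and period until arrest.

## Worked example

```python
from mitoclock import RateParams, sweep_r

print(sweep_r(RateParams(), [0.5, 0.8, 1.5, 2.5]))
```

```
     r       regime  n_fixed_points  period_min  amplitude_nM  baseline_nM
0  0.5   stable_low               1         NaN           NaN          NaN
1  0.8  oscillatory               1   59.042553     19.506455    41.913601
2  1.5  oscillatory               1  217.800000     43.793887    48.932404
3  2.5  stable_high               1         NaN           NaN          NaN
```

At `r = 0.5` the Cdc25-dominated system rests at a low cyclin B steady
state (~39 nM); at `r = 2.5` Wee1 dominance arrests it at high cyclin
(~100 nM, the synthesis/basal-degradation balance).  In between the system
oscillates, and the stronger double-negative feedback at `r = 1.5` gives
slower cycles (218 vs 59 min) with larger amplitude (44 vs 20 nM) and
higher baseline — the tunability axis the energy model moves along as ATP
is consumed.

A command-line interface mirrors the library:

```
mitoclock run-recipe --recipe fig3c --seed 1 --outdir out/
mitoclock simulate --mode ssa --omega 50 --seed 1 --out run.csv
mitoclock analyze trace_table.csv --outdir features/
```

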