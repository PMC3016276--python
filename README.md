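# islsim

An agent-based **in silico liver**: a stochastic, discrete-time simulator of
xenobiotic disposition in Monte Carlo-sampled hepatic lobules, together with
the Monte Carlo experiment runner and the similarity-measure validation
framework used to compare simulated outflow profiles against reference
profiles.

## The model

The liver's functional unit, the lobule, is represented as a directed
acyclic flow network: blood enters at portal-vein (PV) tracts, traverses
**sinusoidal segments** (SS) arranged in zones, and drains into the central
vein (CV). Each lobule's graph structure and segment geometry are Monte
Carlo sampled, so every lobule realization is different.

A sinusoidal segment is a discretized tube:

- a blood **Core** (plug flow, `CoreFlowRate` grid rows per cycle),
- three concentric 2D grids — **Space A** (rim), **Space B** (endothelial
  layer), **Space C** (hepatocyte layer) — on which compounds perform a
  downstream-biased random walk (`SinusoidTurbo`, `StepsPerCycle`) and jump
  radially between spaces with the `S2E/E2S/E2D/D2E` jump probabilities,
- a **BileCanal** (Space D) adjacent to Space C with Core-like dynamics.

Space B/C grid points hold endothelial cells and hepatocytes with densities
`ECDensity`/`HepDensity`; each cell contains `BindersPerCellMin..Max`
binders. A compound entering a cell may be bound for `SoluteBindingCycles`
cycles with probability `SoluteBindingProb`. While bound in a hepatocyte, an
enzyme runs one Bernoulli(`MetabolismProb`) metabolism trial per cycle up to
and including the last bound cycle, so the per-binding metabolism
probability is

    P(metabolized | binding) = 1 - (1 - MetabolismProb)^SoluteBindingCycles
                             = 1 - 0.8^15 ≈ 0.9648  (reference values)

Metabolism destroys the compound and creates exactly one metabolite, which a
draw against the compound's `BileRatio` routes either into the BileCanal
(toward the bile duct, BD) or back into the intracellular space. Dosing is
an impulse: `Dosage` compound objects are injected into the PV inlets in a
single cycle (`DosageCycle`).

The validation observable is the **outflow profile**: the fraction of the
dose collected at the CV per 0.5 s interval. The **Similarity Measure (SM)**
scores a profile against a target band `d·(1 ± σ/μ)` around a reference
curve `d`; a profile with SM ≥ 80% is designated experimentally
indistinguishable from the reference. Reference curves come from a linear
two-compartment ODE model, from a synthetic gamma-variate generator, or from
a user-supplied time/value table.

## Worked example

```python
from islsim import ExperimentConfig, ISLParams, TopologyConfig, run_experiment

config = ExperimentConfig(
    params=ISLParams(Dosage=1000),                     # reference values otherwise
    topology=TopologyConfig(n_zones=1, nodes_per_zone=(1,)),
    n_samples=28,
    base_seed=42,
)
result = run_experiment(config)
print("samples:       ", result.n_samples)
print("dose at CV:    ", round(result.mean_profile.fractions.sum(), 4))
print("peak interval: ", result.mean_profile.interval_starts[
    result.mean_profile.fractions.argmax()], "s")
print("mean |d_n - d_n-1|:", round(float(abs(result.finite_diffs).mean()), 6))
```

prints

```
samples:        28
dose at CV:     0.0848
peak interval:  2.5 s
mean |d_n - d_n-1|: 0.000105
```

i.e. in this configuration about 8% of the dosed compound survives
first-pass extraction and reaches the CV (the rest is metabolized; roughly
half the metabolite leaves via the bile duct), the surviving outflow peaks
shortly after the bolus, and the mean profile's finite differences
`d_n − d_{n−1}` — the smoothness/asymptote diagnostic — are small because 28
lobule samples average out single-lobule noise.

The same experiment from the shell, plus validation against a synthetic
reference:

```sh
islsim run --samples 28 --seed 42 --out results/run1 --nodes-per-zone 9,6,3
islsim synth-ref --out results/ref.csv --cv 0.334
islsim validate --profile results/run1/cv_profile.csv \
                --reference results/ref.csv --cv 0.334 --threshold 80
```

`validate` exits 0 when SM ≥ threshold and 2 otherwise.

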