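# Methods

This note documents the model implemented by `islsim`, the choices made
where the design was genuinely open, and what the test suite's synthetic
conditions do and do not establish.

## Lobule flow networks

A lobule is a zone-layered directed acyclic graph. Zone-1 nodes are
portal-vein inlets, last-zone nodes are central-vein outlets, and edges only
run from zone *i* to zone *i + 1*, each sampled independently with
probability `edge_prob` (default 0.6). After sampling, the graph is
repaired: every non-outlet node gets out-degree ≥ `min_out_degree` and every
non-inlet node at least one predecessor, each repair edge drawn uniformly.
This guarantees acyclicity and full PV→CV connectivity by construction,
while keeping multiple distinct flow paths. The default desk-scale topology
is 3 zones of 9/6/3 segments; the zone structure, node counts and edge
density are configurable because lobule micro-anatomy is not constrained by
the outflow observable this package targets. There is no 3D embedding.

Each node carries a sinusoidal segment of one of two categories — short &
wide (circumference 24, probability `SSTypeRatio` = 0.550) or long & narrow
(circumference 10). Segment length in grid rows is drawn from a shifted
gamma distribution; the second gamma parameter is read as a **rate**
(scale = 1/β), giving mean lengths ≈ 11.8 rows (short/wide: α = 1,
β = 0.085, shift 0) and ≈ 96.7 rows (long/narrow: α = 8, β = 0.075,
shift −10). The scale reading would give sub-row lengths for both
categories, which is degenerate and contradicts the category names; both
readings remain selectable (`gamma_beta_is_rate`), as does an odds
interpretation of `SSTypeRatio` (`ss_ratio_as_odds`). Lengths are rounded
half-up and clamped at one row.

## Per-cycle dynamics

One simulation cycle applies the sub-phases in a fixed order: dosing (once,
at `DosageCycle`) → bound-compound updates → cell exit, then cell
entry/binding → space walk + radial jumps → Core advection → BileCanal
advection → inter-segment transfer with CV/BD logging. All randomness comes
from one `random.Random` stream per lobule (seeded `base_seed +
sample_index`), so runs are exactly reproducible and independent of how
samples are distributed over workers.

Movement rules and the reasoning behind the open choices:

- **Core.** Plug flow at `CoreFlowRate` rows/cycle. The exchange between
  the Core and the surrounding rim is not covered by the published
  parameter vocabulary, so two documented parameters were introduced:
  `core_exit_prob` (default 0.5) — per-cycle probability that a Core
  entity steps sideways into Space A — and `rim_to_core_prob` (default
  0.5) — per-cycle probability that a Space A entity whose outward jump
  failed re-enters the Core.
- **Space walk.** `StepsPerCycle` (2) sub-steps per cycle; each sub-step
  moves one row downstream with probability `SinusoidTurbo` (0.25),
  otherwise to a uniform von-Neumann neighbour. Columns wrap (the grid is a
  tube); upstream moves at row 0 clamp; downstream moves past the last row
  put the entity in the segment's blood outlet buffer. The expected
  downstream drift is therefore `SinusoidTurbo` rows per sub-step away from
  boundaries, which the tests check empirically. "Forward bias" admits
  other readings; P(forced downstream sub-step) was chosen as the simplest
  that reproduces a tunable drift.
- **Radial jumps.** Once per cycle, outward first (A→B at 0.85, B→C at
  0.85), inward only if outward fails (B→A at 0.15, C→B at 0.15). The
  outward bias funnels compound toward the hepatocyte layer. The B→C
  transition uses the `E2DJumpProb` value: its row in the published
  parameter table carries an inconsistent prose description, but the name
  pattern and the A/B/C layering identify it as B→C.
- **Cells and binding.** Space B/C points hold cells with probability
  `ECDensity`/`HepDensity` (0.9 each); binder endowments are
  Uniform{`BindersPerCellMin`..`Max`} (125/125 → exactly 125). A
  membrane-crossing compound standing on a cell point enters the cell; with
  a free binder it is bound with probability `SoluteBindingProb` (0.75) for
  `SoluteBindingCycles` (15) cycles. Unbound intracellular entities exit to
  their host grid point the next cycle. Sucrose (`MembraneCrossing` No)
  never enters cells, so it never binds, is never metabolized, and produces
  no biliary output — it is a pure extracellular flow marker.
- **Metabolism.** While bound in a hepatocyte, one Bernoulli
  (`MetabolismProb` = 0.2) trial per cycle up to and including the last
  bound cycle; hence P(metabolism | binding) = 1 − 0.8¹⁵ ≈ 0.9648, which
  the tests verify against simulation. Endothelial binders only hold and
  release. Metabolism conserves the object count 1:1: the compound is
  destroyed and one metabolite is created at the same location, routed into
  the BileCanal with probability `BileRatio` (0.5 for the dosed compound)
  or left intracellular. Metabolites cross membranes but are never bound
  (`bindable` false), and their own `BileRatio` is 0. A metabolite takes no
  actions during its creation cycle.
- **Bile.** BileCanal dynamics mirror the Core: `CoreFlowRate` rows/cycle,
  no internal capacity. `BileCanalCirc` (1) caps only the hand-off from one
  segment's bile buffer to each successor per cycle (FIFO; the excess stays
  queued); at outlets the hand-off to the bile duct is uncapped.
- **Transfer.** Blood-buffer entities move to the Core row 0 of a uniformly
  chosen successor (uniform column), or are logged at the CV and destroyed
  at outlets. Conservation — dose = in-system + CV log + BD log — holds at
  every cycle and is asserted in the tests.

## Experiments and observables

An experiment runs M Monte Carlo lobule samples (round-robin over N
workers; loads differ by at most one; results are independent of N because
seeding is by sample index). CV/BD exits are binned into 0.5 s collection
intervals as dose fractions scaled by `SoluteScale`; the cycle-to-seconds
calibration is not fixed by the source material, so `seconds_per_cycle`
defaults to 0.5 s (one collection interval per cycle) and is configurable.
Runs are capped at `max_cycles` (480, i.e. 240 s); hitting the cap flags the
sample as truncated, never silently. The validation profile counts the
dosed species at the CV only; metabolites reaching the CV and the bile duct
are binned separately. The statistics stage averages per-sample profiles,
computes per-interval variances, and takes finite differences
d_n − d_{n−1} of the mean profile as the smoothness/asymptote diagnostic.

Under the reference parameterization, first-pass extraction of the dosed
compound is near-total: with 0.9 cell densities, automatic cell entry, 0.75
binding probability and ≈ 0.965 metabolism per hepatocyte binding, only a
small percentage of the dose survives to the CV, and many metabolites are
still in transit at the run cap. The CV profile is correspondingly sparse,
and sample-to-sample variability is heavy-tailed (a lobule that happens to
draw short segments passes far more compound). This shapes the statistical
choices below.

## Similarity measure and references

The target band around a reference profile d is relative:
lower = d·(1 − cv) clamped at 0, upper = d·(1 + cv), with cv = σ/μ = 0.334
by default. The absolute reading d ± cv is dimensionally inconsistent with
a coefficient of variation but remains available (`relative=False`). Band
membership is boundary-inclusive; SM = 100·(points inside)/(points total);
the validation threshold defaults to 80%. SM is scored on the experiment's
mean profile (not pooled per-sample observations).

The two-compartment co-simulation reference solves dA1/dt =
−(k10 + k12)A1 + k21·A2, dA2/dt = k12·A1 − k21·A2, A1(0) = dose, A2(0) = 0
with the matrix exponential (exact for a linear system) and reports the
exact per-interval eliminated fraction (E(t_{n+1}) − E(t_n))/dose,
E = dose − A1 − A2, making it commensurable with the simulator's
per-interval outflow fractions and conserving mass to round-off. Tests
check the k12 = k21 = 0 single-exponential limit at 1e−8 and an independent
fine-step integrator at 1e−6.

The synthetic reference generator stands in for wet-lab bolus outflow data
(no such dataset ships with the package). It produces a gamma-variate curve
g(t) ∝ τ^(shape−1)·e^(−τ), τ = (t − t_lag)/scale, on 0–120 s at 0.5 s with
a sharp leading peak (mode at t_lag + (shape − 1)·scale) and a slow decay,
normalized to a total recovered fraction ≤ 1 (default 0.9), with optional
multiplicative Gaussian noise clamped at zero. Defaults (shape 2, scale
8 s, lag 4 s) put the peak near 12 s. It emulates the *shape* of a
single-pass perfusion profile, not any particular compound's kinetics:
validating against it demonstrates that the SM machinery discriminates, not
that the simulator reproduces any real liver.

## Test-scale choices

Monte Carlo checks run at desk scale, chosen once for statistical adequacy:

- Convergence with sample size uses 20 replicate experiment pairs at M = 7
  vs M = 28 with 1,000-compound doses and single-zone, single-segment
  lobules — the configuration with the densest per-sample event stream, so
  the variance estimate is informative. Var(mean profile) is estimated
  within each experiment (across-sample variance, ddof = 1, divided by M):
  its expectation is exactly σ²/M, and pooling over all samples makes the
  M = 7 : M = 28 ratio concentrate near 4. Estimating the same quantity
  across the 20 replicate means instead is unstable at this event density
  (the heavy-tailed per-lobule profiles give the 20-replicate variance
  estimator too few effective degrees of freedom).
- The end-to-end validation trend (mean SM rises with M against a band
  built from the simulator's own M = 56 mean profile) is tested at M = 7 vs
  M = 28 over 5 seeds. At substantially smaller reference sizes the trend
  can invert: a relative CV band around an under-resolved, sparse reference
  is vanishingly narrow in absolute terms, so better-populated profiles
  score worse. The trend statement therefore applies to adequately resolved
  references only.
- Binomial-oracle checks (bile routing, binding fraction, per-binding
  metabolism, cell placement) use ≥ 10⁴ events and 3-standard-error
  acceptance, the conventional Monte Carlo tolerance.

What passing these tests shows: the mechanisms implement their stated
stochastic rules, conservation is exact, and the experiment machinery has
the correct convergence behaviour. What they do not show: agreement with
any wet-lab outflow profile — the referent datasets are not available, and
the synthetic reference is a shape stand-in.

## Known limitations

- No intra-lobule zonation of enzyme levels; one dosed species plus its
  metabolite per run; no extraction-ratio outputs.
- The cycle→seconds calibration is a package default, not a fitted value.
- Long-narrow segments frequently leave entities in transit at the 480-cycle
  cap under the reference parameterization (flagged as truncation).
- The in-process worker pool reproduces the partitioning semantics of a
  distributed master/worker executive, not its wire protocol or fault
  behaviour.
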