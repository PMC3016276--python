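"""Monte Carlo experiment runner: partitioning, per-sample runs, aggregation.

An experiment executes M independent Monte Carlo lobule samples.  Each
sample builds its own flow graph and dynamics from an independent seed
(``base_seed + sample_index``), so results are identical whether samples run
serially or on an in-process worker pool, and regardless of the worker
count.  CV and BD exit events are binned into fixed-width collection
intervals (0.5 s by default) as dose fractions; the statistics stage
averages the per-sample profiles, computes per-interval variances and the
finite differences d_n - d_{n-1} of the mean profile, the smoothness /
asymptote diagnostic.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ExitRecord, LobuleRunResult, run_lobule
from .lobule import TopologyConfig, build_lobule_graph
from .params import ISLParams

__all__ = [
    "ExperimentConfig",
    "OutflowProfile",
    "SampleResult",
    "MCResult",
    "partition_samples",
    "run_lobule_sample",
    "bin_events",
    "aggregate_profiles",
    "finite_differences",
    "run_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    params: ISLParams = field(default_factory=ISLParams)
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    n_samples: int = 7
    n_workers: int = 1
    base_seed: int = 0
    collection_interval: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.collection_interval <= 0:
            raise ValueError("collection_interval must be > 0")

    @property
    def n_intervals(self) -> int:
        span = self.params.max_cycles * self.params.seconds_per_cycle
        return max(1, math.ceil(span / self.collection_interval - 1e-9))


@dataclass
class OutflowProfile:
    """Dose fraction collected per collection interval at one endpoint."""

    interval_starts: np.ndarray  # seconds, left bin edges
    fractions: np.ndarray        # SoluteScale-scaled dose fraction per interval
    route: str                   # "CV" | "BD"
    species: str

    def __post_init__(self) -> None:
        self.interval_starts = np.asarray(self.interval_starts, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.interval_starts.shape != self.fractions.shape:
            raise ValueError("interval_starts and fractions must align")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be non-negative")

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass
class SampleResult:
    sample_index: int
    seed: int
    cv_profile: OutflowProfile       # dosed species at the central vein
    bd_profile: OutflowProfile       # metabolite at the bile duct
    cv_metabolite: OutflowProfile    # metabolite escaping via the central vein
    cv_log: list[ExitRecord]
    bd_log: list[ExitRecord]
    run: LobuleRunResult

    @property
    def truncated(self) -> bool:
        return self.run.truncated


@dataclass
class MCResult:
    per_sample_profiles: list[OutflowProfile]
    mean_profile: OutflowProfile
    per_interval_variance: np.ndarray
    finite_diffs: np.ndarray
    n_samples: int
    samples: list[SampleResult] = field(default_factory=list)


def partition_samples(M: int, N: int) -> list[list[int]]:
    """Round-robin assignment of M sample indices over N workers.

    Loads differ by at most one and the assignments form a disjoint cover of
    ``{0..M-1}``.
    """
    if N < 1:
        raise ValueError("need at least one worker")
    if M < 0:
        raise ValueError("sample count must be non-negative")
    return [[i for i in range(M) if i % N == w] for w in range(N)]


def bin_events(
    log: list[ExitRecord],
    collection_interval: float,
    seconds_per_cycle: float,
    Dosage: int,
    SoluteScale: float,
    n_intervals: int,
    route: str,
    species: str,
) -> OutflowProfile:
    """Bin exit events into dose fractions per collection interval.

    ``fraction_n = SoluteScale * count{t_exit in [t_n, t_n + interval)} / Dosage``
    with ``t_exit = exit_cycle * seconds_per_cycle``.  A zero dosage yields
    an all-zero profile rather than a division error.
    """
    starts = np.arange(n_intervals) * collection_interval
    counts = np.zeros(n_intervals)
    for rec in log:
        if rec.exit_cycle < 0:
            raise ValueError(f"negative exit cycle for entity {rec.entity_id}")
        idx = int(rec.exit_cycle * seconds_per_cycle / collection_interval)
        if 0 <= idx < n_intervals:
            counts[idx] += 1
    fractions = counts * (SoluteScale / Dosage) if Dosage > 0 else counts * 0.0
    return OutflowProfile(interval_starts=starts, fractions=fractions, route=route, species=species)


def run_lobule_sample(config: ExperimentConfig, sample_index: int) -> SampleResult:
    """Execute one Monte Carlo lobule sample (graph build + dynamics + binning)."""
    seed = config.base_seed + sample_index
    rng = random.Random(seed)
    params = config.params
    graph = build_lobule_graph(config.topology, params, rng)
    run = run_lobule(graph, params, rng)
    dosed_name = params.compound_name
    common = dict(
        collection_interval=config.collection_interval,
        seconds_per_cycle=params.seconds_per_cycle,
        Dosage=params.Dosage,
        SoluteScale=params.SoluteScale,
        n_intervals=config.n_intervals,
    )
    cv_profile = bin_events(
        [r for r in run.cv_log if r.species == dosed_name],
        route="CV", species=dosed_name, **common,
    )
    cv_metabolite = bin_events(
        [r for r in run.cv_log if r.species != dosed_name],
        route="CV", species="metabolite", **common,
    )
    bd_profile = bin_events(run.bd_log, route="BD", species="metabolite", **common)
    return SampleResult(
        sample_index=sample_index,
        seed=seed,
        cv_profile=cv_profile,
        bd_profile=bd_profile,
        cv_metabolite=cv_metabolite,
        cv_log=run.cv_log,
        bd_log=run.bd_log,
        run=run,
    )


def finite_differences(profile: OutflowProfile | np.ndarray) -> np.ndarray:
    """Successive differences d_n - d_{n-1} of a profile (length n - 1)."""
    values = profile.fractions if isinstance(profile, OutflowProfile) else np.asarray(profile, float)
    if len(values) < 2:
        raise ValueError("need at least two intervals for finite differences")
    return np.diff(values)


def aggregate_profiles(profiles: list[OutflowProfile]) -> MCResult:
    """Average per-sample profiles into a mean profile with variances.

    Per-interval variance is the population variance across samples (a single
    sample therefore has zero variance everywhere).
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    base = profiles[0]
    for p in profiles[1:]:
        if len(p) != len(base) or not np.allclose(p.interval_starts, base.interval_starts):
            raise ValueError("profiles must share an identical binning")
        if p.route != base.route or p.species != base.species:
            raise ValueError("profiles must share route and species")
    stack = np.vstack([p.fractions for p in profiles])
    mean = stack.mean(axis=0)
    variance = stack.var(axis=0)
    mean_profile = OutflowProfile(
        interval_starts=base.interval_starts.copy(),
        fractions=mean,
        route=base.route,
        species=base.species,
    )
    diffs = finite_differences(mean_profile) if len(mean_profile) >= 2 else np.array([])
    return MCResult(
        per_sample_profiles=list(profiles),
        mean_profile=mean_profile,
        per_interval_variance=variance,
        finite_diffs=diffs,
        n_samples=len(profiles),
    )


def run_experiment(config: ExperimentConfig) -> MCResult:
    """Run all M samples and aggregate their CV profiles.

    Samples are seeded by sample index, never by worker, so the result is
    independent of the partitioning.  With ``n_workers > 1`` samples are
    dispatched over an in-process worker pool (threads; the partition is the
    same round-robin schedule a distributed master would use).
    """
    M, N = config.n_samples, config.n_workers
    results: list[SampleResult | None] = [None] * M
    if N == 1 or M == 1:
        for i in range(M):
            results[i] = _run_indexed(config, i)
    else:
        from concurrent.futures import ThreadPoolExecutor

        assignment = partition_samples(M, N)
        with ThreadPoolExecutor(max_workers=N) as pool:
            futures = {}
            for worker_load in assignment:
                for i in worker_load:
                    futures[i] = pool.submit(_run_indexed, config, i)
            for i, fut in futures.items():
                results[i] = fut.result()
    samples = [r for r in results if r is not None]
    mc = aggregate_profiles([s.cv_profile for s in samples])
    mc.samples = samples
    return mc


def _run_indexed(config: ExperimentConfig, sample_index: int) -> SampleResult:
    try:
        return run_lobule_sample(config, sample_index)
    except Exception as exc:  # re-raise with the failing sample attached
        raise RuntimeError(f"lobule sample {sample_index} failed: {exc}") from exc
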