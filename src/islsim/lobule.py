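"""Monte Carlo generation of the lobule flow network.

A lobule is modelled as a zone-layered directed acyclic graph.  Blood enters
at portal-vein (PV) tracts, which feed every node of the first zone, flows
along edges that only ever point from zone *i* to zone *i + 1*, and drains
from the last zone into the central vein (CV).  Each node carries a
sinusoidal segment (SS): a discretized tube with a circumference (grid
columns) fixed by its category and a length (grid rows) drawn from a shifted
gamma distribution.  Two SS categories — short & wide versus long & narrow —
provide variety in compound travel paths; which category a node receives is
a Bernoulli draw governed by ``SSTypeRatio``.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .params import ISLParams

__all__ = [
    "SSCategory",
    "SSCategoryParams",
    "SinusoidSegmentSpec",
    "TopologyConfig",
    "LobuleGraph",
    "category_params",
    "sample_ss_category",
    "sample_ss_length",
    "build_lobule_graph",
]


class SSCategory(str, Enum):
    SHORT_WIDE = "short_wide"
    LONG_NARROW = "long_narrow"


@dataclass(frozen=True)
class SSCategoryParams:
    """Geometry distribution of one SS category.

    ``length_beta`` is the second gamma parameter; by default it is read as a
    *rate* (scale = 1/beta), which yields mean lengths of roughly 12 rows for
    the short/wide and 97 rows for the long/narrow category.  Read as a scale
    it would give sub-grid-row lengths, so the rate reading is the default
    (switchable via ``beta_is_rate``).
    """

    category: SSCategory
    circumference: int
    length_shape: float
    length_beta: float
    length_shift: float

    def __post_init__(self) -> None:
        if self.circumference < 1:
            raise ValueError("circumference must be >= 1")
        if self.length_shape <= 0 or self.length_beta <= 0:
            raise ValueError("gamma parameters must be > 0")

    def mean_length(self, beta_is_rate: bool = True) -> float:
        """Expected value of the shifted gamma draw (before rounding/clamping)."""
        scale = 1.0 / self.length_beta if beta_is_rate else self.length_beta
        return self.length_shift + self.length_shape * scale


@dataclass(frozen=True)
class SinusoidSegmentSpec:
    segment_id: int
    category: SSCategory
    circumference: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.circumference < 1:
            raise ValueError("circumference must be >= 1")


@dataclass(frozen=True)
class TopologyConfig:
    """Shape of the zone-layered flow graph.

    Defaults give a desk-scale lobule: three zones of 9, 6 and 3 segments,
    each zone-i node connected to each zone-(i+1) node with probability
    ``edge_prob``, repaired afterwards so that every segment lies on at least
    one PV-to-CV path.
    """

    n_zones: int = 3
    nodes_per_zone: tuple[int, ...] = (9, 6, 3)
    edge_prob: float = 0.6
    min_out_degree: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")
        if len(self.nodes_per_zone) != self.n_zones:
            raise ValueError("nodes_per_zone must have n_zones entries")
        if any(n < 1 for n in self.nodes_per_zone):
            raise ValueError("every zone needs at least one node")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0,1]")
        if self.min_out_degree < 1:
            raise ValueError("min_out_degree must be >= 1")


@dataclass
class LobuleGraph:
    """One Monte Carlo realization of a lobule flow network."""

    segments: list[SinusoidSegmentSpec]
    edges: list[tuple[int, int]]
    inlets: list[int]
    outlets: list[int]
    successors: dict[int, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.successors = {s.segment_id: [] for s in self.segments}
        for src, dst in self.edges:
            self.successors[src].append(dst)
        self.validate()

    def segment(self, segment_id: int) -> SinusoidSegmentSpec:
        return self._by_id[segment_id]

    @property
    def _by_id(self) -> dict[int, SinusoidSegmentSpec]:
        return {s.segment_id: s for s in self.segments}

    def validate(self) -> None:
        """Check acyclicity and full PV-to-CV connectivity."""
        ids = {s.segment_id for s in self.segments}
        if not self.inlets or not self.outlets:
            raise ValueError("graph needs at least one inlet and one outlet")
        for src, dst in self.edges:
            if src not in ids or dst not in ids:
                raise ValueError(f"edge ({src},{dst}) references unknown segment")
        # acyclicity via Kahn's algorithm
        indeg = {i: 0 for i in ids}
        for _, dst in self.edges:
            indeg[dst] += 1
        queue = [i for i in ids if indeg[i] == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for nxt in self.successors[node]:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    queue.append(nxt)
        if seen != len(ids):
            raise ValueError("flow graph contains a cycle")
        # forward reachability from inlets
        reach = set(self.inlets)
        stack = list(self.inlets)
        while stack:
            for nxt in self.successors[stack.pop()]:
                if nxt not in reach:
                    reach.add(nxt)
                    stack.append(nxt)
        if reach != ids:
            raise ValueError(f"segments unreachable from PV: {sorted(ids - reach)}")
        # backward reachability to outlets
        preds: dict[int, list[int]] = {i: [] for i in ids}
        for src, dst in self.edges:
            preds[dst].append(src)
        drain = set(self.outlets)
        stack = list(self.outlets)
        while stack:
            for prv in preds[stack.pop()]:
                if prv not in drain:
                    drain.add(prv)
                    stack.append(prv)
        if drain != ids:
            raise ValueError(f"segments that cannot reach CV: {sorted(ids - drain)}")

    # -- debug / fixture export --------------------------------------------
    def write(self, edges_path: str | Path, segments_path: str | Path) -> None:
        """Write the edge list (``src<TAB>dst`` lines) and segment table CSV."""
        with open(edges_path, "w") as fh:
            for src, dst in self.edges:
                fh.write(f"{src}\t{dst}\n")
        with open(segments_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["segment_id", "category", "circumference", "length"])
            for s in self.segments:
                writer.writerow([s.segment_id, s.category.value, s.circumference, s.length])

    @classmethod
    def read(
        cls,
        edges_path: str | Path,
        segments_path: str | Path,
        inlets: list[int],
        outlets: list[int],
    ) -> "LobuleGraph":
        edges: list[tuple[int, int]] = []
        with open(edges_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    src, dst = line.split("\t")
                    edges.append((int(src), int(dst)))
        segments: list[SinusoidSegmentSpec] = []
        with open(segments_path, newline="") as fh:
            for row in csv.DictReader(fh):
                segments.append(
                    SinusoidSegmentSpec(
                        segment_id=int(row["segment_id"]),
                        category=SSCategory(row["category"]),
                        circumference=int(row["circumference"]),
                        length=int(row["length"]),
                    )
                )
        return cls(segments=segments, edges=edges, inlets=inlets, outlets=outlets)


def category_params(params: ISLParams) -> dict[SSCategory, SSCategoryParams]:
    """Extract the two SS category geometries from a parameter vector."""
    return {
        SSCategory.SHORT_WIDE: SSCategoryParams(
            category=SSCategory.SHORT_WIDE,
            circumference=params.DirSinCirc,
            length_shape=params.DirSinLenAlpha,
            length_beta=params.DirSinLenBeta,
            length_shift=params.DirSinLenShift,
        ),
        SSCategory.LONG_NARROW: SSCategoryParams(
            category=SSCategory.LONG_NARROW,
            circumference=params.TortSinCirc,
            length_shape=params.TortSinLenAlpha,
            length_beta=params.TortSinLenBeta,
            length_shift=params.TortSinLenShift,
        ),
    }


def sample_ss_category(u: float, ratio: float, as_odds: bool = False) -> SSCategory:
    """Map a uniform draw to a segment category.

    ``ratio`` is interpreted as P(short_wide); with ``as_odds=True`` it is
    instead read as the odds short:long, i.e. P = ratio / (1 + ratio).
    """
    if not 0.0 <= u < 1.0:
        raise ValueError(f"u must be in [0,1), got {u}")
    if as_odds:
        if ratio < 0:
            raise ValueError("odds ratio must be >= 0")
        p = ratio / (1.0 + ratio)
    else:
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"ratio must be in [0,1], got {ratio}")
        p = ratio
    return SSCategory.SHORT_WIDE if u < p else SSCategory.LONG_NARROW


def sample_ss_length(
    cat_params: SSCategoryParams, rng: random.Random, beta_is_rate: bool = True
) -> int:
    """Draw a segment length (grid rows) from the shifted gamma distribution.

    Rounds half-up and clamps at 1 row.
    """
    scale = 1.0 / cat_params.length_beta if beta_is_rate else cat_params.length_beta
    draw = rng.gammavariate(cat_params.length_shape, scale)
    value = cat_params.length_shift + draw
    if not math.isfinite(value):
        raise ValueError(f"non-finite length draw: {value}")
    return max(1, math.floor(value + 0.5))


def build_lobule_graph(
    topology: TopologyConfig,
    params: ISLParams,
    rng: random.Random | None = None,
) -> LobuleGraph:
    """Monte Carlo sample one lobule flow graph.

    Every first-zone node is a PV inlet and every last-zone node a CV outlet.
    Edges are sampled independently between consecutive zones; the graph is
    then repaired so each non-outlet node has out-degree >= ``min_out_degree``
    and each non-inlet node is fed by at least one predecessor, guaranteeing
    that every segment lies on a PV-to-CV path.
    """
    if rng is None:
        rng = random.Random(topology.seed)
    cats = category_params(params)

    zones: list[list[int]] = []
    next_id = 0
    for count in topology.nodes_per_zone:
        zones.append(list(range(next_id, next_id + count)))
        next_id += count

    segments: list[SinusoidSegmentSpec] = []
    for zone in zones:
        for sid in zone:
            cat = sample_ss_category(rng.random(), params.SSTypeRatio, params.ss_ratio_as_odds)
            cp = cats[cat]
            length = sample_ss_length(cp, rng, params.gamma_beta_is_rate)
            segments.append(
                SinusoidSegmentSpec(
                    segment_id=sid,
                    category=cat,
                    circumference=cp.circumference,
                    length=length,
                )
            )

    edges: set[tuple[int, int]] = set()
    for upstream, downstream in zip(zones[:-1], zones[1:]):
        for src in upstream:
            for dst in downstream:
                if rng.random() < topology.edge_prob:
                    edges.add((src, dst))
        # repair: out-degree floor for upstream nodes
        for src in upstream:
            out = [d for s, d in edges if s == src]
            deficit = min(topology.min_out_degree, len(downstream)) - len(out)
            if deficit > 0:
                candidates = [d for d in downstream if (src, d) not in edges]
                for dst in rng.sample(candidates, deficit):
                    edges.add((src, dst))
        # repair: every downstream node must be fed
        for dst in downstream:
            if not any(d == dst for _, d in edges):
                edges.add((rng.choice(upstream), dst))

    return LobuleGraph(
        segments=segments,
        edges=sorted(edges),
        inlets=list(zones[0]),
        outlets=list(zones[-1]),
    )
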