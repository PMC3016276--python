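"""Shared fixtures: scripted RNG, hand-built lobule graphs, reduced configs."""

from __future__ import annotations

import random

import pytest

from islsim import ISLParams, LobuleGraph, SSCategory, SinusoidSegmentSpec, TopologyConfig


class ScriptedRNG(random.Random):
    """RNG whose next draws can be forced, falling back to a seeded stream.

    ``queue`` entries are consumed by ``random()`` in order; ``gamma_queue``
    feeds ``gammavariate``.  Everything else (and exhausted queues) delegates
    to a deterministic seeded stream.
    """

    def __init__(self, seed: int = 0, queue: list[float] | None = None,
                 gamma_queue: list[float] | None = None,
                 int_queue: list[int] | None = None) -> None:
        super().__init__(seed)
        self.queue = list(queue or [])
        self.gamma_queue = list(gamma_queue or [])
        self.int_queue = list(int_queue or [])

    def random(self) -> float:
        if self.queue:
            return self.queue.pop(0)
        return super().random()

    def randrange(self, *args, **kwargs) -> int:
        if self.int_queue:
            return self.int_queue.pop(0)
        return super().randrange(*args, **kwargs)

    def gammavariate(self, alpha: float, beta: float) -> float:
        if self.gamma_queue:
            return self.gamma_queue.pop(0)
        return super().gammavariate(alpha, beta)


def chain_graph(lengths: list[int], circumference: int = 4) -> LobuleGraph:
    """A linear chain of segments with prescribed lengths (single PV->CV path)."""
    segments = [
        SinusoidSegmentSpec(
            segment_id=i,
            category=SSCategory.SHORT_WIDE,
            circumference=circumference,
            length=length,
        )
        for i, length in enumerate(lengths)
    ]
    edges = [(i, i + 1) for i in range(len(lengths) - 1)]
    return LobuleGraph(
        segments=segments, edges=edges, inlets=[0], outlets=[len(lengths) - 1]
    )


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


@pytest.fixture
def make_chain():
    return chain_graph


@pytest.fixture
def default_params() -> ISLParams:
    return ISLParams()


@pytest.fixture
def reduced_params() -> ISLParams:
    """Desk-scale conditions for runtime-sensitive Monte Carlo checks."""
    return ISLParams(Dosage=1000)


@pytest.fixture
def small_topology() -> TopologyConfig:
    return TopologyConfig(n_zones=2, nodes_per_zone=(3, 2), edge_prob=0.6)
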