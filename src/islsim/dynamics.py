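"""Per-cycle stochastic update rules inside and between sinusoidal segments.

Each sinusoidal segment (SS) is a discretized tube: a blood Core surrounded
by three identically sized 2D grids (Spaces A, B, C — rim, endothelial layer,
hepatocyte layer) plus the bile canaliculus (BileCanal, Space D) adjacent to
Space C.  Grid columns wrap around the tube circumference; rows run along the
flow axis, increasing downstream, and clamp at the ends (except that moving
past the last row means leaving the segment).

One simulation cycle applies, in a fixed order: bolus dosing (once), bound
compound updates (metabolism trials / timer decrements), cell exit and
entry/binding, the biased random walk plus inter-space jumps, Core advection,
BileCanal advection, and finally inter-segment transfer with CV/BD logging.

All stochastic decisions draw from a single ``random.Random`` stream, so a
lobule run is fully reproducible from its seed.
"""

from __future__ import annotations

import itertools
import random
from collections import deque
from dataclasses import dataclass, field
from enum import Enum

from .lobule import LobuleGraph, SinusoidSegmentSpec
from .params import ISLParams, SpeciesProperties

__all__ = [
    "Compartment",
    "CellKind",
    "MobileEntity",
    "SSState",
    "LobuleState",
    "RunCounters",
    "ExitRecord",
    "place_cells",
    "dose_bolus",
    "advance_core",
    "walk_in_space",
    "attempt_jump",
    "attempt_cell_entry_and_binding",
    "update_bound",
    "create_and_route_metabolite",
    "advance_bile",
    "transfer_at_outlets",
    "step_lobule",
    "run_lobule",
]


class Compartment(Enum):
    CORE = "Core"
    SPACE_A = "SpaceA"
    SPACE_B = "SpaceB"
    SPACE_C = "SpaceC"
    BILE_CANAL = "BileCanal"
    IN_CELL = "InCell"


class CellKind(Enum):
    ENDOTHELIAL = "endothelial"
    HEPATOCYTE = "hepatocyte"


# which cell grid backs which space
_SPACE_OF_KIND = {CellKind.ENDOTHELIAL: Compartment.SPACE_B, CellKind.HEPATOCYTE: Compartment.SPACE_C}
_KIND_OF_SPACE = {v: k for k, v in _SPACE_OF_KIND.items()}

_WALK_SPACES = (Compartment.SPACE_A, Compartment.SPACE_B, Compartment.SPACE_C)


class MobileEntity:
    """A compound or metabolite percolating through the lobule.

    A single entity maps to many molecules of its referent compound.  State
    is its location (segment, compartment, grid row/column), its species and
    — while sequestered by a binder — the remaining bound cycles plus the
    kind of the host cell.
    """

    __slots__ = (
        "entity_id",
        "species",
        "segment_id",
        "compartment",
        "row",
        "col",
        "bound_remaining",
        "cell_kind",
        "alive",
        "freeze_cycle",
    )

    def __init__(
        self,
        entity_id: int,
        species: SpeciesProperties,
        segment_id: int,
        compartment: Compartment,
        row: int,
        col: int,
    ) -> None:
        self.entity_id = entity_id
        self.species = species
        self.segment_id = segment_id
        self.compartment = compartment
        self.row = row
        self.col = col
        self.bound_remaining = 0
        self.cell_kind: CellKind | None = None
        self.alive = True
        # metabolites take no actions during their creation cycle
        self.freeze_cycle = -1

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"MobileEntity({self.entity_id}, {self.species.name}, seg={self.segment_id}, "
            f"{self.compartment.value}, r={self.row}, c={self.col}, "
            f"bound={self.bound_remaining})"
        )


class SSState:
    """Mutable per-segment state: cell grids, binder counts, outlet buffers.

    Cell grids are row-major nested lists: ``ec[row][col]`` / ``hep[row][col]``
    hold -1 where no cell sits, otherwise the number of free binders;
    ``*_total`` holds the binder endowment drawn at construction.  The bile
    outlet buffer is a FIFO queue because hand-off to successors is capacity
    limited by ``BileCanalCirc``.
    """

    __slots__ = (
        "spec",
        "ec_free",
        "ec_total",
        "hep_free",
        "hep_total",
        "blood_buffer",
        "bile_buffer",
    )

    def __init__(self, spec: SinusoidSegmentSpec) -> None:
        self.spec = spec
        rows, cols = spec.length, spec.circumference
        self.ec_free = [[-1] * cols for _ in range(rows)]
        self.ec_total = [[-1] * cols for _ in range(rows)]
        self.hep_free = [[-1] * cols for _ in range(rows)]
        self.hep_total = [[-1] * cols for _ in range(rows)]
        self.blood_buffer: list[MobileEntity] = []
        self.bile_buffer: deque[MobileEntity] = deque()

    # (free, total) grids for the cell kind backing a space
    def grids(self, kind: CellKind) -> tuple[list[list[int]], list[list[int]]]:
        if kind is CellKind.ENDOTHELIAL:
            return self.ec_free, self.ec_total
        return self.hep_free, self.hep_total

    def cell_count(self, kind: CellKind) -> int:
        free, _ = self.grids(kind)
        return sum(1 for row in free for v in row if v >= 0)


@dataclass
class ExitRecord:
    entity_id: int
    species: str
    route: str  # "CV" | "BD"
    exit_cycle: int


@dataclass
class RunCounters:
    """Event tallies used by invariants and the validation targets."""

    bindings_started: int = 0
    bindings_metabolized: int = 0          # hepatocyte bindings ending in metabolism
    bindings_released: int = 0             # all bindings ending in release
    bindings_released_hepatocyte: int = 0  # subset of the above in hepatocytes
    metabolites_created: int = 0
    metabolites_to_bile: int = 0

    @property
    def bindings_completed(self) -> int:
        return self.bindings_metabolized + self.bindings_released

    @property
    def hepatocyte_bindings_completed(self) -> int:
        return self.bindings_metabolized + self.bindings_released_hepatocyte


class LobuleState:
    """Full mutable state of one lobule run."""

    def __init__(self, graph: LobuleGraph, params: ISLParams, rng: random.Random) -> None:
        self.graph = graph
        self.params = params
        self.rng = rng
        self.ss: dict[int, SSState] = {s.segment_id: SSState(s) for s in graph.segments}
        self.entities: list[MobileEntity] = []
        self.cv_log: list[ExitRecord] = []
        self.bd_log: list[ExitRecord] = []
        self.counters = RunCounters()
        self.dosed = False
        self.cycle = 0
        self._id_counter = itertools.count()
        self.dosed_species = params.dosed_species()
        self.metabolite_sp = params.metabolite_species()
        for state in self.ss.values():
            place_cells(state, params, rng)

    def new_id(self) -> int:
        return next(self._id_counter)

    # -- conservation bookkeeping ------------------------------------------
    def total_accounted(self) -> int:
        return len(self.entities) + len(self.cv_log) + len(self.bd_log)


def place_cells(ss: SSState, params: ISLParams, rng: random.Random) -> SSState:
    """Populate Space B with endothelial cells and Space C with hepatocytes.

    Each grid point independently receives a cell with probability
    ``ECDensity`` / ``HepDensity``; each cell's binder endowment is drawn
    Uniform{BindersPerCellMin..Max}.
    """
    bmin, bmax = params.BindersPerCellMin, params.BindersPerCellMax
    for density, (free, total) in (
        (params.ECDensity, (ss.ec_free, ss.ec_total)),
        (params.HepDensity, (ss.hep_free, ss.hep_total)),
    ):
        for r in range(ss.spec.length):
            free_r, total_r = free[r], total[r]
            for c in range(ss.spec.circumference):
                if rng.random() < density:
                    n = bmin if bmin == bmax else rng.randint(bmin, bmax)
                    free_r[c] = n
                    total_r[c] = n
    return ss


def dose_bolus(lob: LobuleState, cycle: int) -> int:
    """Impulse dose: create ``Dosage`` compound objects in the PV inlets.

    Entities are placed in the Core at row 0, spread round-robin over inlet
    segments and uniformly over circumference columns.  May only run once per
    lobule, at ``DosageCycle``.
    """
    params = lob.params
    if lob.dosed:
        raise RuntimeError("dose_bolus called twice for the same lobule run")
    if cycle != params.DosageCycle:
        raise ValueError(f"dosing only at DosageCycle={params.DosageCycle}, got cycle {cycle}")
    inlets = lob.graph.inlets
    if not inlets:
        raise ValueError("lobule has no inlet segments")
    for i in range(params.Dosage):
        seg = inlets[i % len(inlets)]
        circ = lob.ss[seg].spec.circumference
        lob.entities.append(
            MobileEntity(
                entity_id=lob.new_id(),
                species=lob.dosed_species,
                segment_id=seg,
                compartment=Compartment.CORE,
                row=0,
                col=lob.rng.randrange(circ),
            )
        )
    lob.dosed = True
    return params.Dosage


def advance_core(lob: LobuleState, entity: MobileEntity) -> None:
    """Core advection for one entity: sideways exit or downstream advance.

    With probability ``core_exit_prob`` the entity steps out of the plug flow
    into Space A at its current grid point; otherwise it advances
    ``CoreFlowRate`` rows and, past the last row, lands in the segment's
    blood outlet buffer.
    """
    params = lob.params
    ss = lob.ss[entity.segment_id]
    if params.core_exit_prob > 0.0 and lob.rng.random() < params.core_exit_prob:
        entity.compartment = Compartment.SPACE_A
        return
    entity.row += params.CoreFlowRate
    if entity.row >= ss.spec.length:
        entity.row = ss.spec.length - 1
        ss.blood_buffer.append(entity)


def walk_in_space(lob: LobuleState, entity: MobileEntity) -> bool:
    """Biased random walk in Spaces A-C; returns True if the entity exited.

    ``StepsPerCycle`` sub-steps; each sub-step moves one row downstream with
    probability ``SinusoidTurbo``, else to a uniformly chosen von-Neumann
    neighbour.  Columns wrap around the circumference; moving upstream at
    row 0 clamps; moving downstream past the last row puts the entity in the
    blood outlet buffer.
    """
    params = lob.params
    rng = lob.rng
    ss = lob.ss[entity.segment_id]
    length = ss.spec.length
    circ = ss.spec.circumference
    row, col = entity.row, entity.col
    for _ in range(params.StepsPerCycle):
        if rng.random() < params.SinusoidTurbo:
            row += 1
        else:
            d = rng.randrange(4)
            if d == 0:
                row += 1
            elif d == 1:
                row = row - 1 if row > 0 else 0
            elif d == 2:
                col = col + 1 if col + 1 < circ else 0
            else:
                col = col - 1 if col > 0 else circ - 1
        if row >= length:
            entity.row, entity.col = length - 1, col
            ss.blood_buffer.append(entity)
            return True
    entity.row, entity.col = row, col
    return False


def attempt_jump(lob: LobuleState, entity: MobileEntity) -> None:
    """One-per-cycle radial transition between Core-adjacent spaces.

    The outward jump (A->B, B->C) is tried first; only if it fails is the
    inward jump (B->A, C->B) tried.  Space A entities whose outward jump
    fails may instead re-enter the Core with probability ``rim_to_core_prob``.
    Grid position is preserved across jumps.
    """
    params = lob.params
    rng = lob.rng
    comp = entity.compartment
    if comp is Compartment.SPACE_A:
        if rng.random() < params.S2EJumpProb:
            entity.compartment = Compartment.SPACE_B
        elif params.rim_to_core_prob > 0.0 and rng.random() < params.rim_to_core_prob:
            entity.compartment = Compartment.CORE
    elif comp is Compartment.SPACE_B:
        if rng.random() < params.E2DJumpProb:
            entity.compartment = Compartment.SPACE_C
        elif rng.random() < params.E2SJumpProb:
            entity.compartment = Compartment.SPACE_A
    elif comp is Compartment.SPACE_C:
        # no space beyond C for an extracellular entity: only the inward jump
        if rng.random() < params.D2EJumpProb:
            entity.compartment = Compartment.SPACE_B


def attempt_cell_entry_and_binding(lob: LobuleState, entity: MobileEntity) -> bool:
    """Cell entry at the entity's grid point, with an optional binding draw.

    Species that do not cross membranes never enter.  On entry the entity
    becomes intracellular; if its species is bindable, the cell has a free
    binder and a Bernoulli(``SoluteBindingProb``) draw succeeds, the entity
    is sequestered for ``SoluteBindingCycles`` cycles and the binder is
    claimed.  Otherwise it sits intracellular-unbound and exits the cell the
    next cycle.  Returns True if the entity entered a cell.
    """
    if not entity.species.membrane_crossing:
        return False
    kind = _KIND_OF_SPACE.get(entity.compartment)
    if kind is None:
        return False
    ss = lob.ss[entity.segment_id]
    free, _ = ss.grids(kind)
    n_free = free[entity.row][entity.col]
    if n_free < 0:  # no cell here
        return False
    params = lob.params
    entity.compartment = Compartment.IN_CELL
    entity.cell_kind = kind
    if entity.species.bindable and n_free > 0 and lob.rng.random() < params.SoluteBindingProb:
        entity.bound_remaining = params.SoluteBindingCycles
        free[entity.row][entity.col] = n_free - 1
        lob.counters.bindings_started += 1
    return True


def create_and_route_metabolite(lob: LobuleState, parent: MobileEntity) -> MobileEntity:
    """Replace a metabolized compound by a metabolite (1:1 conservation).

    A draw against the parent species' ``BileRatio`` routes the metabolite
    into the BileCanal at the row of the hosting hepatocyte; otherwise it is
    left intracellular-unbound in that hepatocyte.  The parent is destroyed
    and the metabolite appended to the lobule roster (1 parent -> 1
    metabolite, so the object count is conserved).
    """
    metabolite = MobileEntity(
        entity_id=lob.new_id(),
        species=lob.metabolite_sp,
        segment_id=parent.segment_id,
        compartment=Compartment.IN_CELL,
        row=parent.row,
        col=parent.col,
    )
    metabolite.freeze_cycle = lob.cycle
    lob.counters.metabolites_created += 1
    if lob.rng.random() < parent.species.bile_ratio:
        metabolite.compartment = Compartment.BILE_CANAL
        lob.counters.metabolites_to_bile += 1
    else:
        metabolite.cell_kind = CellKind.HEPATOCYTE
    parent.alive = False
    lob.entities.append(metabolite)
    return metabolite


def update_bound(lob: LobuleState, entity: MobileEntity) -> str:
    """Per-cycle update of a bound entity: metabolism trial, decrement, release.

    In a hepatocyte the enzyme runs one Bernoulli(``MetabolismProb``) trial
    every cycle up to and including the last bound cycle; success destroys
    the compound, frees the binder and creates a routed metabolite.  In an
    endothelial cell the binder only holds and releases.  Returns one of
    ``"metabolized" | "released" | "bound"``.
    """
    params = lob.params
    ss = lob.ss[entity.segment_id]
    kind = entity.cell_kind
    assert kind is not None and entity.bound_remaining > 0
    if kind is CellKind.HEPATOCYTE and lob.rng.random() < params.MetabolismProb:
        free, _ = ss.grids(kind)
        free[entity.row][entity.col] += 1
        lob.counters.bindings_metabolized += 1
        create_and_route_metabolite(lob, entity)
        return "metabolized"
    entity.bound_remaining -= 1
    if entity.bound_remaining == 0:
        free, _ = ss.grids(kind)
        free[entity.row][entity.col] += 1
        lob.counters.bindings_released += 1
        if kind is CellKind.HEPATOCYTE:
            lob.counters.bindings_released_hepatocyte += 1
        return "released"
    return "bound"


def advance_bile(lob: LobuleState, entity: MobileEntity) -> None:
    """BileCanal advection: identical dynamics to the Core, no capacity limit
    inside the canal; past the last row the metabolite queues in the bile
    outlet buffer."""
    ss = lob.ss[entity.segment_id]
    entity.row += lob.params.CoreFlowRate
    if entity.row >= ss.spec.length:
        entity.row = ss.spec.length - 1
        ss.bile_buffer.append(entity)


def transfer_at_outlets(lob: LobuleState, cycle: int) -> None:
    """Move buffered entities to successor segments or log them at CV/BD.

    Blood-buffer entities enter the Core (row 0, uniform column) of a
    uniformly chosen successor, or are logged at the central vein and
    destroyed if the segment is an outlet.  Bile-buffer metabolites move to
    the successor's BileCanal, at most ``BileCanalCirc`` per edge per cycle
    (FIFO; excess stays queued); at outlets the hand-off to the bile duct is
    not capacity limited.
    """
    params = lob.params
    rng = lob.rng
    removed: list[MobileEntity] = []
    for sid in sorted(lob.ss):
        ss = lob.ss[sid]
        succs = lob.graph.successors[sid]
        if ss.blood_buffer:
            for entity in ss.blood_buffer:
                if succs:
                    tgt = succs[rng.randrange(len(succs))] if len(succs) > 1 else succs[0]
                    entity.segment_id = tgt
                    entity.compartment = Compartment.CORE
                    entity.row = 0
                    entity.col = rng.randrange(lob.ss[tgt].spec.circumference)
                else:
                    lob.cv_log.append(
                        ExitRecord(entity.entity_id, entity.species.name, "CV", cycle)
                    )
                    removed.append(entity)
            ss.blood_buffer.clear()
        if ss.bile_buffer:
            if not succs:
                while ss.bile_buffer:
                    entity = ss.bile_buffer.popleft()
                    lob.bd_log.append(
                        ExitRecord(entity.entity_id, entity.species.name, "BD", cycle)
                    )
                    removed.append(entity)
            else:
                quota = params.BileCanalCirc * len(succs)
                moved = 0
                while ss.bile_buffer and moved < quota:
                    entity = ss.bile_buffer.popleft()
                    tgt = succs[moved % len(succs)]
                    entity.segment_id = tgt
                    entity.compartment = Compartment.BILE_CANAL
                    entity.row = 0
                    entity.col = 0
                    moved += 1
    if removed:
        gone = {id(e) for e in removed}
        lob.entities = [e for e in lob.entities if id(e) not in gone]


def step_lobule(lob: LobuleState, cycle: int) -> None:
    """Advance the lobule one simulation cycle (fixed sub-phase order).

    Order: dose (at ``DosageCycle``) -> bound updates -> cell exit + cell
    entry/binding -> space walk + jumps -> Core advection -> BileCanal
    advection -> inter-segment transfer and CV/BD logging.
    """
    params = lob.params
    lob.cycle = cycle
    if cycle == params.DosageCycle and not lob.dosed:
        dose_bolus(lob, cycle)

    # phase: bound entities (metabolism trials / timers).  Metabolism swaps
    # the parent for a metabolite; the roster is compacted afterwards.
    bound = [e for e in lob.entities if e.bound_remaining > 0]
    for entity in bound:
        update_bound(lob, entity)
    if lob.counters.bindings_metabolized:
        lob.entities = [e for e in lob.entities if e.alive]

    # phase: cell traffic.  Entry candidates are collected before exits are
    # applied so a compound leaving a cell cannot re-enter it the same cycle;
    # metabolites created this cycle rest until the next one.
    entry_candidates = [
        e
        for e in lob.entities
        if e.bound_remaining == 0
        and e.compartment in (Compartment.SPACE_B, Compartment.SPACE_C)
        and e.species.membrane_crossing
    ]
    for entity in lob.entities:
        if (
            entity.compartment is Compartment.IN_CELL
            and entity.bound_remaining == 0
            and entity.freeze_cycle != cycle
        ):
            entity.compartment = _SPACE_OF_KIND[entity.cell_kind]
            entity.cell_kind = None
    for entity in entry_candidates:
        attempt_cell_entry_and_binding(lob, entity)

    # phase: space walk + radial jumps
    walkers = [
        e for e in lob.entities if e.compartment in _WALK_SPACES and e.bound_remaining == 0
    ]
    for entity in walkers:
        if not walk_in_space(lob, entity):
            attempt_jump(lob, entity)

    # phase: Core advection
    for entity in lob.entities:
        if entity.compartment is Compartment.CORE:
            advance_core(lob, entity)

    # phase: BileCanal advection
    for entity in lob.entities:
        if entity.compartment is Compartment.BILE_CANAL and entity.freeze_cycle != cycle:
            advance_bile(lob, entity)

    # phase: inter-segment transfer, CV/BD logging
    transfer_at_outlets(lob, cycle)
    lob.cycle = cycle + 1


@dataclass
class LobuleRunResult:
    cv_log: list[ExitRecord]
    bd_log: list[ExitRecord]
    counters: RunCounters
    cycles_run: int
    truncated: bool
    n_remaining: int


def run_lobule(
    graph: LobuleGraph, params: ISLParams, rng: random.Random
) -> LobuleRunResult:
    """Run one lobule from dosing until all entities exited or ``max_cycles``."""
    lob = LobuleState(graph, params, rng)
    cycle = 0
    while cycle < params.max_cycles:
        step_lobule(lob, cycle)
        cycle += 1
        if lob.dosed and not lob.entities:
            break
    truncated = bool(lob.entities)
    return LobuleRunResult(
        cv_log=lob.cv_log,
        bd_log=lob.bd_log,
        counters=lob.counters,
        cycles_run=cycle,
        truncated=truncated,
        n_remaining=len(lob.entities),
    )
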