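"""Per-cycle update rules: cells, dosing, movement, binding, metabolism, bile."""

from __future__ import annotations

import math
import random

import pytest

from islsim import Compartment, ISLParams, LobuleState
from islsim.dynamics import (
    CellKind,
    MobileEntity,
    advance_bile,
    advance_core,
    attempt_cell_entry_and_binding,
    attempt_jump,
    create_and_route_metabolite,
    dose_bolus,
    place_cells,
    run_lobule,
    step_lobule,
    transfer_at_outlets,
    update_bound,
    walk_in_space,
)

from conftest import ScriptedRNG, chain_graph


def make_lobule(
    lengths=(6,), params: ISLParams | None = None, rng=None, circumference: int = 4
) -> LobuleState:
    params = params or ISLParams()
    rng = rng if rng is not None else random.Random(0)
    return LobuleState(chain_graph(list(lengths), circumference), params, rng)


NO_CELLS = dict(ECDensity=0.0, HepDensity=0.0)
PLUG_FLOW = dict(
    core_exit_prob=0.0,
    rim_to_core_prob=0.0,
    S2EJumpProb=0.0,
    E2SJumpProb=0.0,
    E2DJumpProb=0.0,
    D2EJumpProb=0.0,
    **NO_CELLS,
)


class TestPlaceCells:
    def test_zero_density_places_no_cells(self):
        lob = make_lobule(params=ISLParams(**NO_CELLS))
        ss = lob.ss[0]
        assert ss.cell_count(CellKind.ENDOTHELIAL) == 0
        assert ss.cell_count(CellKind.HEPATOCYTE) == 0

    def test_degenerate_uniform_gives_exact_binder_count(self):
        lob = make_lobule(params=ISLParams(ECDensity=1.0, HepDensity=1.0))
        ss = lob.ss[0]
        for grid in (ss.ec_free, ss.hep_free):
            assert all(v == 125 for row in grid for v in row)

    def test_cell_count_matches_binomial_oracle(self):
        # 0.9 density over 1000 grid points: within 3 binomial SDs of 900
        params = ISLParams(ECDensity=0.9, HepDensity=0.9)
        lob = make_lobule(lengths=(100,), params=params, circumference=10,
                          rng=random.Random(12))
        n, p = 1000, 0.9
        sd = math.sqrt(n * p * (1 - p))
        for kind in CellKind:
            assert abs(lob.ss[0].cell_count(kind) - n * p) < 3 * sd

    def test_binder_endowment_uniform_between_min_and_max(self):
        params = ISLParams(BindersPerCellMin=10, BindersPerCellMax=20,
                           ECDensity=1.0, HepDensity=1.0)
        lob = make_lobule(lengths=(50,), params=params, circumference=10,
                          rng=random.Random(3))
        values = [v for row in lob.ss[0].hep_total for v in row]
        assert min(values) == 10 and max(values) == 20
        assert abs(sum(values) / len(values) - 15.0) < 0.5


class TestDosing:
    def test_impulse_creates_dosage_entities_at_dosage_cycle(self):
        params = ISLParams(Dosage=5000, DosageCycle=2, **NO_CELLS)
        lob = make_lobule(lengths=(200,), params=params)
        for cycle in range(3):
            before = len(lob.entities)
            step_lobule(lob, cycle)
            if cycle < 2:
                assert before == 0 and len(lob.entities) == 0
        assert lob.total_accounted() == 5000

    def test_zero_dose_runs_empty(self):
        params = ISLParams(Dosage=0)
        result = run_lobule(chain_graph([5]), params, random.Random(0))
        assert result.cv_log == [] and result.bd_log == []

    def test_placement_in_core_row_zero_of_inlet(self):
        params = ISLParams(Dosage=7)
        lob = make_lobule(lengths=(10,), params=params, circumference=24)
        dose_bolus(lob, params.DosageCycle)
        assert len(lob.entities) == 7
        for e in lob.entities:
            assert e.segment_id == 0
            assert e.compartment is Compartment.CORE
            assert e.row == 0
            assert 0 <= e.col < 24

    def test_double_dose_rejected(self):
        params = ISLParams(Dosage=5)
        lob = make_lobule(params=params)
        dose_bolus(lob, params.DosageCycle)
        with pytest.raises(RuntimeError):
            dose_bolus(lob, params.DosageCycle)


class TestCoreAndWalk:
    def test_core_advection_advances_one_row(self):
        lob = make_lobule(lengths=(10,), params=ISLParams(core_exit_prob=0.0))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.CORE, row=5, col=0)
        advance_core(lob, e)
        assert e.row == 6 and not lob.ss[0].blood_buffer

    def test_core_boundary_moves_to_blood_buffer(self):
        lob = make_lobule(lengths=(10,), params=ISLParams(core_exit_prob=0.0))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.CORE, row=9, col=0)
        advance_core(lob, e)
        assert lob.ss[0].blood_buffer == [e]

    def test_plug_flow_transit_time_is_closed_form(self, make_chain):
        # no sideways exit, no jumps: transit = ceil(L / CoreFlowRate) cycles
        for L, rate in [(7, 1), (7, 2), (8, 3)]:
            params = ISLParams(Dosage=20, CoreFlowRate=rate, **PLUG_FLOW)
            result = run_lobule(make_chain([L]), params, random.Random(1))
            expected_cycle = params.DosageCycle + math.ceil(L / rate) - 1
            assert all(rec.exit_cycle == expected_cycle for rec in result.cv_log)
            assert len(result.cv_log) == 20

    def test_full_turbo_walk_is_strictly_downstream(self):
        # SinusoidTurbo=1: every sub-step advances a row
        params = ISLParams(SinusoidTurbo=1.0, StepsPerCycle=2, **NO_CELLS)
        lob = make_lobule(lengths=(10,), params=params)
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_A, row=0, col=0)
        lob.entities.append(e)
        walk_in_space(lob, e)
        assert e.row == 2

    def test_column_wraparound_is_toroidal(self):
        params = ISLParams(SinusoidTurbo=0.0, StepsPerCycle=1, **NO_CELLS)
        lob = make_lobule(lengths=(10,), params=params, circumference=24)
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_A, row=5, col=23)
        lob.entities.append(e)
        lob.rng = ScriptedRNG(queue=[0.9], int_queue=[2])  # no turbo; lateral col+1
        walk_in_space(lob, e)
        assert e.col == 0 and e.row == 5
        lob.rng = ScriptedRNG(queue=[0.9], int_queue=[3])  # lateral col-1
        walk_in_space(lob, e)
        assert e.col == 23

    def test_walk_exit_past_last_row_reaches_blood_buffer(self):
        params = ISLParams(SinusoidTurbo=1.0, StepsPerCycle=2, **NO_CELLS)
        lob = make_lobule(lengths=(3,), params=params)
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_B, row=2, col=0)
        lob.entities.append(e)
        assert walk_in_space(lob, e) is True
        assert lob.ss[0].blood_buffer == [e]

    def test_mean_downstream_displacement_matches_turbo(self):
        # E[d(row)] per sub-step = SinusoidTurbo away from the boundaries
        params = ISLParams(SinusoidTurbo=0.25, StepsPerCycle=1, **NO_CELLS)
        lob = make_lobule(lengths=(100_000,), params=params, circumference=8,
                          rng=random.Random(99))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_A, row=50_000, col=0)
        lob.entities.append(e)
        n = 100_000
        start = e.row
        for _ in range(n):
            walk_in_space(lob, e)
        # per sub-step: P(+1) = turbo + (1-turbo)/4, P(-1) = (1-turbo)/4
        drift = (e.row - start) / n
        var_step = 0.25 + 0.75 * 0.5 - 0.25**2  # E[d^2] - E[d]^2 upper bound
        assert abs(drift - 0.25) < 3 * math.sqrt(var_step / n)


class TestJumps:
    def test_outward_jump_spacea_to_spaceb(self):
        lob = make_lobule(params=ISLParams(**NO_CELLS))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_A, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.3])  # 0.3 < 0.850
        attempt_jump(lob, e)
        assert e.compartment is Compartment.SPACE_B
        assert (e.row, e.col) == (2, 1)

    def test_spacec_failed_inward_jump_stays(self):
        lob = make_lobule(params=ISLParams(**NO_CELLS))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.9])  # 0.9 >= 0.150
        attempt_jump(lob, e)
        assert e.compartment is Compartment.SPACE_C

    def test_spacea_can_return_to_core(self):
        lob = make_lobule(params=ISLParams(rim_to_core_prob=0.5, **NO_CELLS))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_A, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.9, 0.2])  # outward fails, core draw succeeds
        attempt_jump(lob, e)
        assert e.compartment is Compartment.CORE

    def test_spaceb_transition_frequencies_match_two_draw_scheme(self):
        # outward tried first: P(->C) = 0.85 exactly; P(->A) = 0.15 * 0.15
        lob = make_lobule(params=ISLParams(**NO_CELLS), rng=random.Random(17))
        n = 100_000
        to_c = to_a = 0
        for _ in range(n):
            e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_B, 2, 1)
            attempt_jump(lob, e)
            to_c += e.compartment is Compartment.SPACE_C
            to_a += e.compartment is Compartment.SPACE_A
        for observed, p in [(to_c, 0.85), (to_a, 0.15 * 0.15)]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed / n - p) < 3 * se


class TestCellEntryAndBinding:
    def hepatocyte_lobule(self, params=None):
        params = params or ISLParams(ECDensity=1.0, HepDensity=1.0)
        return make_lobule(lengths=(5,), params=params)

    def test_non_crossing_species_never_enters(self):
        lob = self.hepatocyte_lobule(ISLParams.for_compound(
            "sucrose", ECDensity=1.0, HepDensity=1.0))
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
        assert attempt_cell_entry_and_binding(lob, e) is False
        assert e.compartment is Compartment.SPACE_C

    def test_binding_claims_binder_and_sets_timer(self):
        lob = self.hepatocyte_lobule()
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.5])  # 0.5 < 0.750
        assert attempt_cell_entry_and_binding(lob, e) is True
        assert e.compartment is Compartment.IN_CELL
        assert e.bound_remaining == 15
        assert lob.ss[0].hep_free[2][1] == 124

    def test_failed_binding_leaves_intracellular_unbound(self):
        lob = self.hepatocyte_lobule()
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.9])
        attempt_cell_entry_and_binding(lob, e)
        assert e.compartment is Compartment.IN_CELL
        assert e.bound_remaining == 0
        assert lob.ss[0].hep_free[2][1] == 125

    def test_no_free_binder_means_no_binding(self):
        lob = self.hepatocyte_lobule()
        lob.ss[0].hep_free[2][1] = 0
        e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.0])
        attempt_cell_entry_and_binding(lob, e)
        assert e.bound_remaining == 0

    def test_metabolite_enters_but_never_binds(self):
        lob = self.hepatocyte_lobule()
        e = MobileEntity(0, lob.metabolite_sp, 0, Compartment.SPACE_C, 2, 1)
        lob.rng = ScriptedRNG(queue=[0.0])
        assert attempt_cell_entry_and_binding(lob, e) is True
        assert e.bound_remaining == 0

    def test_binding_fraction_matches_binomial_oracle(self):
        lob = self.hepatocyte_lobule()
        lob.rng = random.Random(23)
        n = 10_000
        bound = 0
        for _ in range(n):
            e = MobileEntity(0, lob.dosed_species, 0, Compartment.SPACE_C, 2, 1)
            attempt_cell_entry_and_binding(lob, e)
            bound += e.bound_remaining > 0
            if e.bound_remaining:
                lob.ss[0].hep_free[2][1] += 1  # restore the binder
        p = 0.75
        assert abs(bound / n - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestBoundUpdates:
    def bind_entity(self, lob, kind: CellKind) -> MobileEntity:
        e = MobileEntity(lob.new_id(), lob.dosed_species, 0, Compartment.IN_CELL, 2, 1)
        e.cell_kind = kind
        e.bound_remaining = lob.params.SoluteBindingCycles
        lob.entities.append(e)
        return e

    def test_endothelial_binder_always_releases_on_schedule(self):
        lob = make_lobule(params=ISLParams(ECDensity=1.0, HepDensity=1.0))
        e = self.bind_entity(lob, CellKind.ENDOTHELIAL)
        lob.ss[0].ec_free[2][1] -= 1
        outcomes = [update_bound(lob, e) for _ in range(15)]
        assert outcomes == ["bound"] * 14 + ["released"]
        assert lob.ss[0].ec_free[2][1] == 125

    def test_zero_metabolism_prob_degenerates_to_release(self):
        params = ISLParams(MetabolismProb=0.0, ECDensity=1.0, HepDensity=1.0)
        lob = make_lobule(params=params)
        e = self.bind_entity(lob, CellKind.HEPATOCYTE)
        lob.ss[0].hep_free[2][1] -= 1
        outcomes = [update_bound(lob, e) for _ in range(15)]
        assert outcomes[-1] == "released"
        assert lob.counters.metabolites_created == 0

    def test_per_binding_metabolism_matches_closed_form(self):
        # one trial per bound cycle: P(metabolized | binding) = 1 - (1-p)^cycles
        params = ISLParams(ECDensity=1.0, HepDensity=1.0)
        lob = make_lobule(params=params, rng=random.Random(31))
        n = 10_000
        for _ in range(n):
            e = self.bind_entity(lob, CellKind.HEPATOCYTE)
            lob.ss[0].hep_free[2][1] -= 1
            while e.bound_remaining > 0:
                if update_bound(lob, e) == "metabolized":
                    break
            lob.entities.clear()
        p = 1 - (1 - 0.2) ** 15
        frac = lob.counters.bindings_metabolized / n
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestMetaboliteRouting:
    def test_routing_threshold_rule(self):
        lob = make_lobule(params=ISLParams(ECDensity=1.0, HepDensity=1.0))
        parent = MobileEntity(0, lob.dosed_species, 0, Compartment.IN_CELL, 2, 1)
        lob.entities.append(parent)
        lob.rng = ScriptedRNG(queue=[0.4])  # 0.4 < BileRatio 0.5 -> bile
        m = create_and_route_metabolite(lob, parent)
        assert m.compartment is Compartment.BILE_CANAL
        assert (m.row, m.col) == (2, 1)
        lob.rng = ScriptedRNG(queue=[0.7])  # 0.7 >= 0.5 -> intracellular
        parent2 = MobileEntity(1, lob.dosed_species, 0, Compartment.IN_CELL, 2, 1)
        lob.entities.append(parent2)
        m2 = create_and_route_metabolite(lob, parent2)
        assert m2.compartment is Compartment.IN_CELL

    def test_object_count_conserved_one_to_one(self):
        lob = make_lobule(params=ISLParams(ECDensity=1.0, HepDensity=1.0))
        parent = MobileEntity(0, lob.dosed_species, 0, Compartment.IN_CELL, 2, 1)
        lob.entities.append(parent)
        create_and_route_metabolite(lob, parent)
        alive = [e for e in lob.entities if e.alive]
        assert len(alive) == 1 and alive[0].species.name == "metabolite"

    def test_bile_fraction_converges_to_bile_ratio(self):
        lob = make_lobule(params=ISLParams(ECDensity=1.0, HepDensity=1.0),
                          rng=random.Random(41))
        n = 10_000
        for i in range(n):
            parent = MobileEntity(i, lob.dosed_species, 0, Compartment.IN_CELL, 2, 1)
            lob.entities.append(parent)
            create_and_route_metabolite(lob, parent)
            lob.entities.clear()
        p = 0.5
        frac = lob.counters.metabolites_to_bile / lob.counters.metabolites_created
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestBileFlow:
    def test_bile_advection_one_row(self):
        lob = make_lobule(lengths=(10,))
        m = MobileEntity(0, lob.metabolite_sp, 0, Compartment.BILE_CANAL, 3, 0)
        advance_bile(lob, m)
        assert m.row == 4

    def test_simultaneous_advance_without_internal_capacity(self):
        lob = make_lobule(lengths=(4,))
        mets = [
            MobileEntity(i, lob.metabolite_sp, 0, Compartment.BILE_CANAL, 3, 0)
            for i in range(100)
        ]
        for m in mets:
            advance_bile(lob, m)
        assert len(lob.ss[0].bile_buffer) == 100

    def test_bile_handoff_capped_per_edge_fifo(self, make_chain):
        lob = LobuleState(make_chain([5, 5]), ISLParams(BileCanalCirc=1, **NO_CELLS),
                          random.Random(0))
        mets = [
            MobileEntity(i, lob.metabolite_sp, 0, Compartment.BILE_CANAL, 4, 0)
            for i in range(3)
        ]
        lob.entities.extend(mets)
        lob.ss[0].bile_buffer.extend(mets)
        transfer_at_outlets(lob, cycle=10)
        moved = [e for e in mets if e.segment_id == 1]
        assert len(moved) == 1 and moved[0] is mets[0]  # FIFO head
        assert len(lob.ss[0].bile_buffer) == 2

    def test_outlet_logs_and_destroys(self):
        lob = make_lobule(lengths=(5,))
        blood = [
            MobileEntity(i, lob.dosed_species, 0, Compartment.CORE, 4, 0) for i in range(4)
        ]
        lob.entities.extend(blood)
        lob.ss[0].blood_buffer.extend(blood)
        transfer_at_outlets(lob, cycle=9)
        assert len(lob.cv_log) == 4
        assert all(rec.exit_cycle == 9 and rec.route == "CV" for rec in lob.cv_log)
        assert lob.entities == []

    def test_bd_handoff_at_outlet_not_capacity_limited(self):
        lob = make_lobule(lengths=(5,), params=ISLParams(BileCanalCirc=1, **NO_CELLS))
        mets = [
            MobileEntity(i, lob.metabolite_sp, 0, Compartment.BILE_CANAL, 4, 0)
            for i in range(5)
        ]
        lob.entities.extend(mets)
        lob.ss[0].bile_buffer.extend(mets)
        transfer_at_outlets(lob, cycle=3)
        assert len(lob.bd_log) == 5


class TestFullRuns:
    def test_identical_seeds_reproduce_logs(self, small_topology):
        from islsim import build_lobule_graph

        params = ISLParams(Dosage=200, max_cycles=120)
        logs = []
        for _ in range(2):
            rng = random.Random(7)
            graph = build_lobule_graph(small_topology, params, rng)
            result = run_lobule(graph, params, rng)
            logs.append(
                (
                    [(r.entity_id, r.exit_cycle) for r in result.cv_log],
                    [(r.entity_id, r.exit_cycle) for r in result.bd_log],
                )
            )
        assert logs[0] == logs[1]

    def test_sucrose_produces_no_metabolites_and_no_bd_output(self, make_chain):
        params = ISLParams.for_compound("sucrose", Dosage=300, max_cycles=3000)
        result = run_lobule(make_chain([4, 4]), params, random.Random(5))
        assert result.counters.metabolites_created == 0
        assert result.bd_log == []
        assert all(r.species == "sucrose" for r in result.cv_log)
        # extracellular marker is fully recovered at the CV given enough cycles
        assert len(result.cv_log) == 300
        assert not result.truncated

    def test_plug_flow_multi_segment_path_oracle(self, make_chain):
        # fixed 5-segment chain, no jumps/exits: exit cycle follows path lengths
        lengths = [3, 7, 1, 5, 4]
        params = ISLParams(Dosage=50, **PLUG_FLOW)
        result = run_lobule(make_chain(lengths), params, random.Random(2))
        expected = params.DosageCycle + sum(lengths) - 1
        assert len(result.cv_log) == 50
        assert all(rec.exit_cycle == expected for rec in result.cv_log)

    def test_conservation_every_cycle(self, make_chain):
        params = ISLParams(Dosage=150, max_cycles=200)
        lob = LobuleState(make_chain([5, 5]), params, random.Random(13))
        for cycle in range(params.max_cycles):
            step_lobule(lob, cycle)
            if cycle >= params.DosageCycle:
                assert lob.total_accounted() == params.Dosage, f"cycle {cycle}"
            if lob.dosed and not lob.entities:
                break

    def test_binders_return_to_total_after_drainage(self, make_chain):
        params = ISLParams(Dosage=100, max_cycles=5000)
        lob = LobuleState(make_chain([4]), params, random.Random(19))
        for cycle in range(params.max_cycles):
            step_lobule(lob, cycle)
            if lob.dosed and not lob.entities:
                break
        assert not lob.entities, "lobule failed to drain"
        ss = lob.ss[0]
        assert ss.ec_free == ss.ec_total
        assert ss.hep_free == ss.hep_total
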