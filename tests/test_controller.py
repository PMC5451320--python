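"""Controller: arbitration, adaptive dt, and full-simulation invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wcsim import fixtures
from wcsim.controller import (
    SimulationConfig,
    adapt_dt,
    arbitrate,
    collect_requests,
    simulate,
    submodel_stream,
)
from wcsim.engine_boolean import BooleanRule, Effect
from wcsim.engine_ssa import ssa_advance
from wcsim.model_core import Compartment, Formalism, Reaction, Species, Submodel, merge_shared_species
from wcsim.state import ChangeRequest, StateSnapshot


def _req(smid, **deltas):
    return ChangeRequest(submodel_id=smid, deltas=deltas)


class TestArbitrate:
    def test_even_split_with_no_remainder(self):
        decision = arbitrate([_req("s1", A=-3), _req("s2", A=-3)], {"A": 4})
        assert decision.accepted["s1"]["A"] == -2
        assert decision.accepted["s2"]["A"] == -2
        assert decision.committed_counts["A"] == 0
        assert decision.scaled_species == {"A"}

    def test_leftover_unit_goes_to_lowest_submodel_id(self):
        decision = arbitrate([_req("s1", A=-3), _req("s2", A=-3)], {"A": 5})
        assert decision.accepted["s1"]["A"] == -3
        assert decision.accepted["s2"]["A"] == -2
        assert decision.committed_counts["A"] == 0

    def test_largest_remainder_beats_tie_break(self):
        # requests 5 and 2 against a pool of 4: floors 2,1; remainders 6/7, 1/7
        decision = arbitrate([_req("s1", A=-5), _req("s2", A=-2)], {"A": 4})
        assert decision.accepted["s1"]["A"] == -3
        assert decision.accepted["s2"]["A"] == -1

    def test_no_conflict_passes_requests_verbatim(self):
        reqs = [_req("s1", A=-3, B=2), _req("s2", A=-1)]
        decision = arbitrate(reqs, {"A": 10, "B": 0})
        assert decision.scaled_species == set()
        assert decision.accepted == {"s1": {"A": -3, "B": 2}, "s2": {"A": -1}}
        assert decision.committed_counts == {"A": 6, "B": 2}

    def test_production_always_accepted_even_on_empty_pool(self):
        decision = arbitrate([_req("s1", A=7), _req("s2", A=3)], {"A": 0})
        assert decision.scaled_species == set()
        assert decision.committed_counts["A"] == 10

    def test_production_counts_toward_availability(self):
        # pool 0, but s1 produces 6 of A while s2 wants to consume 6
        decision = arbitrate([_req("s1", A=6), _req("s2", A=-6)], {"A": 0})
        assert decision.scaled_species == set()
        assert decision.committed_counts["A"] == 0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        pool=st.integers(0, 50),
        consumptions=st.lists(st.integers(0, 30), min_size=1, max_size=5),
        productions=st.lists(st.integers(0, 10), min_size=1, max_size=5),
    )
    def test_committed_counts_never_negative(self, pool, consumptions, productions):
        reqs = [_req(f"c{i}", A=-c) for i, c in enumerate(consumptions)]
        reqs += [_req(f"p{i}", A=p) for i, p in enumerate(productions)]
        decision = arbitrate(reqs, {"A": pool})
        assert decision.committed_counts["A"] >= 0
        granted = sum(-d["A"] for s, d in decision.accepted.items() if d.get("A", 0) < 0)
        available = pool + sum(productions)
        assert granted <= available
        # consumption is only scaled when genuinely short
        if sum(consumptions) <= available:
            assert decision.scaled_species == set()

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        pool=st.integers(0, 20),
        consumptions=st.lists(st.integers(1, 30), min_size=2, max_size=5),
    )
    def test_arbitration_is_permutation_invariant(self, pool, consumptions):
        reqs = [_req(f"s{i}", A=-c) for i, c in enumerate(consumptions)]
        d1 = arbitrate(reqs, {"A": pool})
        d2 = arbitrate(list(reversed(reqs)), {"A": pool})
        assert d1.accepted == d2.accepted


class TestAdaptDt:
    def _config(self, **kw):
        defaults = dict(t_max=10.0, dt_init=1.0, dt_min=0.125, dt_max=2.0, clean_steps_to_grow=3)
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def _scaled_decision(self):
        return arbitrate([_req("s1", A=-3), _req("s2", A=-3)], {"A": 4})

    def _clean_decision(self):
        return arbitrate([_req("s1", A=-1)], {"A": 10})

    def test_scaling_halves_dt_and_requests_redo(self):
        verdict = adapt_dt(self._scaled_decision(), 1.0, self._config(), 0)
        assert verdict.redo and verdict.next_dt == 0.5

    def test_scaling_at_floor_commits_with_warning(self):
        verdict = adapt_dt(self._scaled_decision(), 0.125, self._config(), 2)
        assert not verdict.redo and verdict.warn
        assert verdict.next_dt == 0.125 and verdict.clean_counter == 0

    def test_retry_budget_exhaustion_commits_with_warning(self):
        verdict = adapt_dt(self._scaled_decision(), 1.0, self._config(max_retries=2), 0, retries=2)
        assert not verdict.redo and verdict.warn

    def test_clean_streak_doubles_dt_up_to_cap(self):
        cfg = self._config()
        verdict = adapt_dt(self._clean_decision(), 0.5, cfg, 2)  # third clean step
        assert verdict.next_dt == 1.0 and verdict.clean_counter == 0
        verdict = adapt_dt(self._clean_decision(), 2.0, cfg, 2)
        assert verdict.next_dt == 2.0  # capped at dt_max

    def test_clean_step_below_streak_keeps_dt(self):
        verdict = adapt_dt(self._clean_decision(), 1.0, self._config(), 0)
        assert not verdict.redo and verdict.next_dt == 1.0 and verdict.clean_counter == 1


def _single_ssa_model(reactions, counts):
    comp = Compartment(id="c")
    sm = Submodel(
        id="only",
        formalism=Formalism.SSA,
        compartments=[comp],
        species=[Species(id=s, compartment="c", initial_count=n) for s, n in counts.items()],
        reactions=reactions,
    )
    return merge_shared_species([sm], {("only", s): s for s in counts})


class TestCollectRequests:
    def test_null_dynamics_yield_zero_requests(self):
        model = _single_ssa_model([], {"A": 5})
        snap = StateSnapshot(0.0, {"A": 5})
        reqs, _ = collect_requests(snap, model.submodels, 1.0, {"only": submodel_stream(0, "only", 0)}, {})
        assert [r.deltas for r in reqs] == [{}]

    def test_invocation_order_is_unobservable(self):
        model, _ = fixtures.make_minimal_cell_model()
        kinetic = [sm for sm in model.submodels if sm.formalism is not Formalism.BOOLEAN]
        snap = StateSnapshot(0.0, model.initial_counts(), model.parameters)
        streams = lambda: {
            sm.id: submodel_stream(5, sm.id, 0) for sm in kinetic if sm.formalism is Formalism.SSA
        }
        fwd, _ = collect_requests(snap, kinetic, 1.0, streams(), {})
        rev, _ = collect_requests(snap, list(reversed(kinetic)), 1.0, streams(), {})
        assert {r.submodel_id: r.deltas for r in fwd} == {r.submodel_id: r.deltas for r in rev}

    def test_disjoint_submodels_request_disjoint_keys(self):
        model = fixtures.make_conversion_chain_model(hybrid=True)
        # make the species sets disjoint by pointing the ODE half at its own pool
        snap = StateSnapshot(0.0, {"A_c": 100, "B_c": 50, "C_c": 0})
        kinetic = sorted(model.submodels, key=lambda s: s.id)
        streams = {
            sm.id: submodel_stream(1, sm.id, 0)
            for sm in kinetic
            if sm.formalism is Formalism.SSA
        }
        reqs, _ = collect_requests(snap, kinetic, 1.0, streams, {})
        interfaces = {sm.id: sm.interface_species for sm in kinetic}
        for r in reqs:
            assert set(r.deltas) <= interfaces[r.submodel_id]


class TestSimulate:
    def test_no_reactions_means_constant_trajectory(self):
        model = _single_ssa_model([], {"A": 7, "B": 3})
        traj = simulate(model, SimulationConfig(t_max=10.0, seed=1))
        assert np.all(traj.counts == traj.counts[0])

    def test_closed_pair_conserves_total(self):
        model = _single_ssa_model(
            [
                Reaction(id="f", reactants={"A": 1}, products={"B": 1}, rate_constant=0.05),
                Reaction(id="b", reactants={"B": 1}, products={"A": 1}, rate_constant=0.05),
            ],
            {"A": 50, "B": 50},
        )
        traj = simulate(model, SimulationConfig(t_max=100.0, dt_init=0.5, dt_min=0.125, dt_max=0.5, seed=3))
        totals = traj.counts.sum(axis=1)
        assert np.all(totals == 100)

    def test_identical_seed_gives_bit_identical_trajectories(self, minimal_cell):
        model, _ = minimal_cell
        cfg = SimulationConfig(t_max=8.0, seed=11)
        t1 = simulate(model, cfg)
        t2 = simulate(model, cfg)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.counts, t2.counts)

    def test_different_seeds_differ(self, minimal_cell):
        model, _ = minimal_cell
        t1 = simulate(model, SimulationConfig(t_max=8.0, seed=1))
        t2 = simulate(model, SimulationConfig(t_max=8.0, seed=2))
        assert not np.array_equal(t1.counts, t2.counts)

    def test_single_ssa_submodel_equals_plain_gillespie(self):
        """With dt ≥ t_max the controller is a plain direct-method run."""
        model = fixtures.make_immigration_death_model()
        t_max = 20.0
        cfg = SimulationConfig(t_max=t_max, dt_init=t_max, dt_min=t_max, dt_max=t_max, seed=9)
        traj = simulate(model, cfg)
        sm = model.submodels[0]
        snap = StateSnapshot(0.0, model.initial_counts())
        res = ssa_advance(snap, sm, t_max, submodel_stream(9, sm.id, 0, 0))
        assert traj.final_counts()["A_c"] == 100 + res.request.deltas.get("A_c", 0)

    def test_boolean_updates_apply_one_step_late(self):
        """A rule firing at step k changes dynamics from step k+1 on."""
        comp = Compartment(id="c")
        sm = Submodel(
            id="source",
            formalism=Formalism.ODE,
            compartments=[comp],
            species=[Species(id="A_c", compartment="c", initial_count=0)],
            reactions=[Reaction(id="make", products={"A_c": 1}, rate_constant=10.0)],
        )
        model = merge_shared_species([sm], {("source", "A_c"): "A_c"})
        model.submodels.append(
            Submodel(
                id="switch",
                formalism=Formalism.BOOLEAN,
                rules=[
                    BooleanRule(
                        id="stop",
                        condition="A_c >= 30",
                        effect=Effect(kind="reaction", target="make", enabled=False),
                    )
                ],
                interface_species={"A_c"},
            )
        )
        cfg = SimulationConfig(t_max=6.0, dt_init=1.0, dt_min=1.0, dt_max=1.0, seed=0)
        traj = simulate(model, cfg)
        # snapshot at A=30 still runs the enabled step (one-step delay), so
        # production halts at exactly 40
        assert traj.counts[:, 0].tolist() == [0, 10, 20, 30, 40, 40, 40]

    def test_fuzzed_hybrid_models_never_go_negative(self):
        for seed in range(1, 41):
            model, _ = fixtures.make_random_hybrid_model(seed)
            cfg = SimulationConfig(t_max=2.0, dt_init=0.5, dt_min=0.125, dt_max=0.5, seed=seed)
            traj = simulate(model, cfg)
            assert traj.counts.min() >= 0, f"seed {seed}"

    def test_validation_failure_aborts_before_stepping(self):
        model = _single_ssa_model([], {"A": 5})
        model.global_species["A"] = Species(id="A", compartment="nowhere", initial_count=5)
        with pytest.raises(ValueError, match="validation"):
            simulate(model, SimulationConfig(t_max=1.0))

    def test_sequential_reference_mode_converges_to_controller_mode(self):
        """The rejected sequential strategy agrees with the controller as dt→0.

        The submodel ids are chosen so the stochastic producer runs first in
        sequential mode: its output is then visible to the deterministic
        consumer within the same step, which is exactly the arrow-of-time
        violation the controller scheme removes.  The modes therefore differ
        at coarse dt and converge as dt shrinks.
        """
        comp = Compartment(id="c")
        def build():
            src = Submodel(
                id="a_src",
                formalism=Formalism.SSA,
                compartments=[comp],
                species=[
                    Species(id="A_c", compartment="c", initial_count=150),
                    Species(id="B_c", compartment="c", initial_count=0),
                ],
                reactions=[
                    Reaction(id="ab", reactants={"A_c": 1}, products={"B_c": 1}, rate_constant=0.2)
                ],
            )
            sink = Submodel(
                id="z_sink",
                formalism=Formalism.ODE,
                compartments=[comp],
                species=[
                    Species(id="B_c", compartment="c", initial_count=0),
                    Species(id="C_c", compartment="c", initial_count=0),
                ],
                reactions=[
                    Reaction(id="bc", reactants={"B_c": 1}, products={"C_c": 1}, rate_constant=0.2)
                ],
            )
            mapping = {
                ("a_src", "A_c"): "A_c",
                ("a_src", "B_c"): "B_c",
                ("z_sink", "B_c"): "B_c",
                ("z_sink", "C_c"): "C_c",
            }
            return merge_shared_species([src, sink], mapping)

        def mean_final(mode, dt, n=80):
            out = []
            for i in range(n):
                cfg = SimulationConfig(
                    t_max=5.0, dt_init=dt, dt_min=dt, dt_max=dt, seed=1000 + i, output_stride=10**6
                )
                out.append(simulate(build(), cfg, mode=mode).final_counts()["C_c"])
            return np.mean(out)

        gaps = [abs(mean_final("controller", dt) - mean_final("sequential", dt)) for dt in (2.0, 0.25)]
        assert gaps[1] < gaps[0]
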