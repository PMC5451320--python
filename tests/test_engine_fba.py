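"""Dynamic FBA engine: bound tightening, LP optimum, flux-to-count conversion."""

import numpy as np
import pytest

from oracles import lp_vertex_max
from wcsim.engine_fba import (
    FbaStatus,
    build_fba_problem,
    fba_advance,
    solve_lp,
)
from wcsim.model_core import (
    Compartment,
    FbaSpec,
    Formalism,
    Reaction,
    Species,
    Submodel,
)
from wcsim.state import StateSnapshot


def _fba_submodel(species, reactions, spec):
    return Submodel(
        id="fba",
        formalism=Formalism.FBA,
        compartments=[Compartment(id="c")],
        species=species,
        reactions=reactions,
        fba=spec,
        interface_species={sp.id for sp in species},
    )


def toy_chain(uptake_ub=10.0):
    """∅→A uptake (bounded), A→biomass growth (objective)."""
    species = [
        Species(id="A", compartment="c", boundary=True),
        Species(id="X", compartment="c"),
        Species(id="biomass", compartment="c", boundary=True),
    ]
    reactions = [
        Reaction(id="uptake", reactants={"A": 1}, products={"X": 1}),
        Reaction(id="growth", reactants={"X": 1}, products={"biomass": 1}),
    ]
    spec = FbaSpec(
        lower_bounds={"uptake": 0.0, "growth": 0.0},
        upper_bounds={"uptake": uptake_ub, "growth": 1e6},
        objective={"growth": 1.0},
    )
    return _fba_submodel(species, reactions, spec)


def parallel_routes():
    """Two routes to biomass, each capped at 6, shared uptake capped at 10."""
    species = [
        Species(id="A", compartment="c", boundary=True),
        Species(id="X", compartment="c"),
        Species(id="biomass", compartment="c", boundary=True),
    ]
    reactions = [
        Reaction(id="uptake", reactants={"A": 1}, products={"X": 1}),
        Reaction(id="route1", reactants={"X": 1}, products={"biomass": 1}),
        Reaction(id="route2", reactants={"X": 1}, products={"biomass": 1}),
    ]
    spec = FbaSpec(
        upper_bounds={"uptake": 10.0, "route1": 6.0, "route2": 6.0},
        objective={"route1": 1.0, "route2": 1.0},
    )
    return _fba_submodel(species, reactions, spec)


class TestBoundTightening:
    @pytest.mark.parametrize(
        "n, dt, static, expected",
        [
            (5, 1.0, 10.0, 5.0),  # min(10, 5/1)
            (0, 1.0, 10.0, 0.0),  # empty pool → no uptake
            (5, 0.5, 10.0, 10.0),  # min(10, 5/0.5)
        ],
    )
    def test_uptake_bound_limited_by_availability(self, n, dt, static, expected):
        sm = toy_chain(uptake_ub=static)
        snap = StateSnapshot(0.0, {"A": n, "biomass": 0, "X": 0})
        problem = build_fba_problem(snap, sm, dt)
        j = problem.reaction_ids.index("uptake")
        assert problem.upper[j] == pytest.approx(expected)

    def test_internal_metabolites_are_steady_state_rows(self):
        sm = toy_chain()
        snap = StateSnapshot(0.0, {"A": 100, "biomass": 0, "X": 0})
        problem = build_fba_problem(snap, sm, 1.0)
        assert problem.internal_ids == ["X"]
        assert problem.boundary_ids == ["A", "biomass"]


class TestSolveLp:
    def test_toy_chain_optimum_is_uptake_capacity(self):
        sm = toy_chain()
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        problem = build_fba_problem(snap, sm, 1.0)
        sol = solve_lp(problem)
        assert sol.status is FbaStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(lp_vertex_max(problem), abs=1e-9)

    def test_degenerate_routes_have_unique_objective(self):
        sm = parallel_routes()
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        problem = build_fba_problem(snap, sm, 1.0)
        sol = solve_lp(problem)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(lp_vertex_max(problem), abs=1e-9)

    def test_contradictory_bounds_are_infeasible_not_silent(self):
        sm = toy_chain()
        sm.fba.lower_bounds["growth"] = 5.0
        sm.fba.upper_bounds["growth"] = 3.0
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        sol = solve_lp(build_fba_problem(snap, sm, 1.0))
        assert sol.status is FbaStatus.INFEASIBLE

    def test_steady_state_and_bounds_hold_at_optimum(self):
        sm = parallel_routes()
        snap = StateSnapshot(0.0, {"A": 7, "biomass": 0, "X": 0})
        problem = build_fba_problem(snap, sm, 1.0)
        sol = solve_lp(problem)
        assert np.max(np.abs(problem.stoichiometry @ sol.fluxes)) < 1e-8
        assert np.all(sol.fluxes >= problem.lower - 1e-8)
        assert np.all(sol.fluxes <= problem.upper + 1e-8)

    def test_objective_monotone_in_bound_relaxation(self):
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        prev = -np.inf
        for cap in (2.0, 5.0, 8.0, 20.0):
            sol = solve_lp(build_fba_problem(snap, toy_chain(uptake_ub=cap), 1.0))
            assert sol.objective_value >= prev - 1e-12
            prev = sol.objective_value


class TestFbaAdvance:
    def test_flux_times_dt_becomes_integer_request(self):
        sm = toy_chain(uptake_ub=5.0)
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        req, _ = fba_advance(snap, sm, 1.0)
        assert req.deltas == {"A": -5, "biomass": 5}
        assert "X" not in req.deltas  # internal metabolite: steady state

    def test_infeasible_lp_degrades_to_flagged_zero_request(self):
        sm = toy_chain()
        sm.fba.lower_bounds["growth"] = 5.0
        sm.fba.upper_bounds["growth"] = 3.0
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        req, _ = fba_advance(snap, sm, 1.0)
        assert req.deltas == {} and req.diagnostics.get("infeasible") is True

    def test_zero_dt_is_a_zero_request(self):
        sm = toy_chain()
        snap = StateSnapshot(0.0, {"A": 1000, "biomass": 0, "X": 0})
        req, _ = fba_advance(snap, sm, 0.0)
        assert req.deltas == {}

    @pytest.mark.parametrize("n_a", [0, 1, 3, 17])
    def test_availability_safety_by_construction(self, n_a):
        """An FBA request alone can never overdraw a boundary pool."""
        sm = toy_chain(uptake_ub=100.0)
        snap = StateSnapshot(0.0, {"A": n_a, "biomass": 0, "X": 0})
        req, _ = fba_advance(snap, sm, 1.0)
        assert req.deltas.get("A", 0) >= -n_a

    def test_carry_accumulates_fractional_flux(self):
        # uptake bound 2.5/s at dt=1 → alternating integer deltas of 2 and 3
        sm = toy_chain(uptake_ub=2.5)
        counts = {"A": 1000, "biomass": 0, "X": 0}
        carry = None
        produced = []
        for _ in range(4):
            req, carry = fba_advance(StateSnapshot(0.0, counts), sm, 1.0, carry)
            for sid, d in req.deltas.items():
                counts[sid] += d
            produced.append(req.deltas["biomass"])
        assert sum(produced) == 10  # 4 × 2.5 exactly, thanks to the carry
        assert sorted(set(produced)) == [2, 3]
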