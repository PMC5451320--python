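"""Dynamic flux balance analysis engine.

Each controller step, the FBA submodel is converted into a linear program:
maximize the objective over fluxes ``v`` subject to steady state for
*internal* metabolites (``S_int · v = 0``), static flux bounds, and an
*availability* constraint that caps the consumption of every boundary
(pool-coupled) species at its current copy number divided by the step
length.  The optimal boundary fluxes times ``dt`` become the submodel's
change request, integerized with the same residual-carry scheme the ODE
engine uses.  Internal metabolites contribute no deltas (they are at steady
state by construction).

Fluxes are in molecules per second, matching the integer pool.  Standard
FBC models in mmol/gDW/h must be rescaled by (cell mass × Avogadro / 3600)
before use.

An infeasible or unbounded program degrades to a zero request with a
diagnostic flag — a cell with halted metabolism — rather than aborting the
simulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .engine_ode import round_with_carry
from .model_core import Submodel
from .state import ChangeRequest, StateSnapshot

_DEFAULT_UB = 1e9  # effectively unbounded, keeps the LP numerically finite


class FbaStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FbaCarry:
    """Per-boundary-species rounding residuals, persisted across steps."""

    residuals: dict[str, float] = field(default_factory=dict)


@dataclass
class FBAProblem:
    """A fully assembled per-step linear program.

    ``stoichiometry`` covers internal metabolites only (the ``S·v = 0``
    rows); ``boundary_stoichiometry`` gives the pool-coupled species' net
    coefficients used for availability constraints and for converting fluxes
    to deltas.  Bounds are already tightened by availability: a reaction
    consuming boundary species ``s`` with coefficient ``-a`` has upper bound
    at most ``n_s / (dt·a)``.
    """

    reaction_ids: list[str]
    internal_ids: list[str]
    boundary_ids: list[str]
    stoichiometry: np.ndarray  # internal × reactions
    boundary_stoichiometry: np.ndarray  # boundary × reactions
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    availability: np.ndarray  # per boundary species, counts / dt


@dataclass
class FBASolution:
    fluxes: np.ndarray
    objective_value: float
    status: FbaStatus


def build_fba_problem(snapshot: StateSnapshot, submodel: Submodel, dt: float) -> FBAProblem:
    """Assemble the step LP with pool-limited exchange bounds.

    Static bounds come from the submodel's :class:`~wcsim.model_core.FbaSpec`
    (default ``[0, +inf)``); the upper bound of every reaction consuming a
    boundary species ``s`` is tightened to ``min(static, n_s / (dt·|a|))``.
    Aggregate availability rows additionally guarantee that the *total*
    consumption of each boundary species across all reactions stays within
    its pool, so an FBA request alone can never drive a pool negative.
    """
    if submodel.fba is None:
        raise ValueError(f"submodel '{submodel.id}' carries no FBA spec")
    if dt <= 0:
        raise ValueError("dt must be positive")
    spec = submodel.fba
    rxns = submodel.reactions
    rids = [r.id for r in rxns]
    boundary = {sp.id for sp in submodel.species if sp.boundary}
    internal_ids = sorted(
        sid for r in rxns for sid in r.species_ids() if sid not in boundary
    )
    internal_ids = sorted(set(internal_ids))
    boundary_ids = sorted(boundary & set().union(*(r.species_ids() for r in rxns)) if rxns else set())

    S_int = np.zeros((len(internal_ids), len(rxns)))
    S_bnd = np.zeros((len(boundary_ids), len(rxns)))
    int_idx = {sid: i for i, sid in enumerate(internal_ids)}
    bnd_idx = {sid: i for i, sid in enumerate(boundary_ids)}
    for j, r in enumerate(rxns):
        for sid, v in r.net_stoichiometry().items():
            if sid in int_idx:
                S_int[int_idx[sid], j] = v
            else:
                S_bnd[bnd_idx[sid], j] = v

    lb = np.array([spec.lower_bounds.get(rid, 0.0) for rid in rids])
    ub = np.array([spec.upper_bounds.get(rid, _DEFAULT_UB) for rid in rids])
    avail = np.array([snapshot.counts[sid] / dt for sid in boundary_ids])
    for j in range(len(rxns)):
        for i, sid in enumerate(boundary_ids):
            a = S_bnd[i, j]
            if a < 0:
                ub[j] = min(ub[j], avail[i] / (-a))

    obj = np.array([spec.objective.get(rid, 0.0) for rid in rids])
    return FBAProblem(
        reaction_ids=rids,
        internal_ids=internal_ids,
        boundary_ids=boundary_ids,
        stoichiometry=S_int,
        boundary_stoichiometry=S_bnd,
        lower=lb,
        upper=ub,
        objective=obj,
        availability=avail,
    )


def solve_lp(problem: FBAProblem) -> FBASolution:
    """Maximize the objective over the flux polytope.

    Infeasible and unbounded programs are reported through ``status``, never
    as silent zeros.  When the flux vector is degenerate the objective value
    is still unique (LP optimal value), which is all downstream code relies
    on.
    """
    n = len(problem.reaction_ids)
    if np.any(problem.lower > problem.upper):
        return FBASolution(np.zeros(n), float("nan"), FbaStatus.INFEASIBLE)
    A_ub = b_ub = None
    if len(problem.boundary_ids):
        # total consumption of each boundary pool ≤ availability
        A_ub = -problem.boundary_stoichiometry
        b_ub = problem.availability
    res = linprog(
        c=-problem.objective,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=problem.stoichiometry if len(problem.internal_ids) else None,
        b_eq=np.zeros(len(problem.internal_ids)) if len(problem.internal_ids) else None,
        bounds=list(zip(problem.lower, problem.upper)),
        method="highs",
    )
    if res.status == 0:
        return FBASolution(np.asarray(res.x), float(-res.fun), FbaStatus.OPTIMAL)
    if res.status == 3:
        return FBASolution(np.zeros(n), float("inf"), FbaStatus.UNBOUNDED)
    return FBASolution(np.zeros(n), float("nan"), FbaStatus.INFEASIBLE)


def fba_advance(
    snapshot: StateSnapshot,
    submodel: Submodel,
    dt: float,
    carry: FbaCarry | None = None,
) -> tuple[ChangeRequest, FbaCarry]:
    """Solve the step LP and convert boundary fluxes to an integer request.

    Deltas are ``round_with_carry(flux · dt)`` per boundary species, floored
    at minus the available pool; internal metabolites contribute nothing.
    ``dt = 0`` or a non-optimal LP yields a zero request (the latter with an
    ``"infeasible"`` diagnostic flag).
    """
    carry = carry or FbaCarry()
    if dt == 0:
        return ChangeRequest(submodel_id=submodel.id), FbaCarry(dict(carry.residuals))
    problem = build_fba_problem(snapshot, submodel, dt)
    sol = solve_lp(problem)
    if sol.status is not FbaStatus.OPTIMAL:
        return (
            ChangeRequest(
                submodel_id=submodel.id,
                diagnostics={"infeasible": True, "fba_status": sol.status.value},
            ),
            FbaCarry(dict(carry.residuals)),
        )
    residuals = dict(carry.residuals)
    deltas: dict[str, int] = {}
    cont = problem.boundary_stoichiometry @ sol.fluxes * dt
    for i, sid in enumerate(problem.boundary_ids):
        d, r = round_with_carry(float(cont[i]), residuals.get(sid, 0.0), floor=-snapshot.counts[sid])
        if d != 0:
            deltas[sid] = d
        if r != 0.0:
            residuals[sid] = r
        else:
            residuals.pop(sid, None)
    request = ChangeRequest(
        submodel_id=submodel.id,
        deltas=deltas,
        diagnostics={"objective_value": sol.objective_value},
    )
    return request, FbaCarry(residuals)
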