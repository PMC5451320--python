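"""Deterministic mass-action engine with residual-carry integerization.

An ODE submodel is integrated with fixed-substep classical Runge–Kutta
(RK4) over one controller step.  Rate laws are *count-based*: a reaction
with constant ``c`` and reactant stoichiometries ``s_i`` contributes
``c * prod_i n_i^{s_i}`` (molecules per second) times its stoichiometry, so
the deterministic and stochastic encodings of the same reaction agree in the
large-count limit with no unit conversion.

Because the global pool is integer-valued, the continuous per-step delta is
rounded to the nearest integer with a per-species *residual carry* persisted
across steps: over any run of k steps the summed integer deltas differ from
the continuous total by less than one molecule per species.  Rounding is
deterministic (no stochastic rounding), so repeated runs are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_core import Reaction, Submodel
from .state import ChangeRequest, EngineNumericError, StateSnapshot

_RESIDUAL_CAP = 1.0 - 1e-9


@dataclass
class OdeCarry:
    """Per-species fractional residuals persisted between steps.

    Each residual lies strictly inside (-1, 1).  A fresh carry (all zeros)
    is the correct initial state.
    """

    residuals: dict[str, float] = field(default_factory=dict)


def round_with_carry(
    continuous_delta: float, residual: float, floor: int | None = None
) -> tuple[int, float]:
    """Integerize ``continuous_delta`` given the prior ``residual``.

    Returns ``(integer_delta, new_residual)`` with
    ``integer_delta + new_residual == continuous_delta + residual`` whenever
    the optional ``floor`` (a lower bound on the integer delta, used to keep
    pools non-negative) is not binding.  When the floor clips the delta the
    residual is adjusted and then capped into (-1, 1); the clipped mass is
    dropped rather than owed forever.
    """
    total = continuous_delta + residual
    d = int(round(total))
    if floor is not None and d < floor:
        d = floor
    r = total - d
    r = max(-_RESIDUAL_CAP, min(_RESIDUAL_CAP, r))
    return d, r


def net_rates(
    counts: Mapping[str, float],
    reactions: Sequence[Reaction],
    volume: float = 1.0,
    parameters: Mapping[str, float] | None = None,
    enabled: Mapping[str, bool] | None = None,
) -> dict[str, float]:
    """Deterministic mass-action net rates, molecules per second per species.

    ``volume`` is accepted for interface symmetry with concentration-based
    rate laws but is inert under the count-based convention used here.
    Negative intermediate values (possible transiently inside an integrator)
    are treated as zero when evaluating rate laws.
    """
    del volume
    rates: dict[str, float] = {}
    for rxn in reactions:
        if enabled is not None and not enabled.get(rxn.id, rxn.enabled):
            continue
        if enabled is None and not rxn.enabled:
            continue
        c = rxn.rate_constant
        if rxn.rate_parameter is not None and parameters and rxn.rate_parameter in parameters:
            c = float(parameters[rxn.rate_parameter])
        v = float(c)
        for sid, s in rxn.reactants.items():
            v *= max(0.0, float(counts[sid])) ** s
        if v == 0.0:
            continue
        for sid, net in rxn.net_stoichiometry().items():
            rates[sid] = rates.get(sid, 0.0) + net * v
    return rates


def ode_advance(
    snapshot: StateSnapshot,
    submodel: Submodel,
    dt: float,
    carry: OdeCarry | None = None,
    h_max: float | None = None,
) -> tuple[ChangeRequest, OdeCarry]:
    """Integrate the submodel over ``[0, dt]`` and integerize the deltas.

    Classical RK4 with ``max(1, ceil(dt / h_max))`` equal substeps
    (``h_max`` defaults to ``dt / 10``).  The continuous delta plus the prior
    residual is rounded to the nearest integer; the new residual is returned
    in a fresh :class:`OdeCarry` (the input carry is not mutated).  The
    integer request never drives the submodel's private copy of any pool
    negative: deltas are floored at minus the available count, with the
    residual adjusted.

    Raises
    ------
    EngineNumericError
        If the state becomes non-finite during integration (names the
        offending species).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    carry = carry or OdeCarry()
    if h_max is None:
        h_max = dt / 10.0
    n_sub = max(1, math.ceil(dt / h_max - 1e-12))
    h = dt / n_sub

    species = sorted(
        set().union(*(r.species_ids() for r in submodel.reactions))
        if submodel.reactions
        else set()
    )
    if not species:
        return ChangeRequest(submodel_id=submodel.id), OdeCarry(dict(carry.residuals))

    idx = {sid: i for i, sid in enumerate(species)}
    y0 = np.array([float(snapshot.counts[sid]) for sid in species])
    params = snapshot.parameters
    enabled = {r.id: snapshot.is_enabled(r) for r in submodel.reactions}

    def f(y: np.ndarray) -> np.ndarray:
        counts = {sid: y[idx[sid]] for sid in species}
        rates = net_rates(counts, submodel.reactions, parameters=params, enabled=enabled)
        out = np.zeros_like(y)
        for sid, v in rates.items():
            out[idx[sid]] = v
        return out

    y = y0.copy()
    for _ in range(n_sub):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            bad = species[int(np.argmax(~np.isfinite(y)))]
            raise EngineNumericError(
                f"non-finite state for species '{bad}' in submodel '{submodel.id}'"
            )

    residuals = dict(carry.residuals)
    deltas: dict[str, int] = {}
    for sid in species:
        cont = float(y[idx[sid]] - y0[idx[sid]])
        d, r = round_with_carry(cont, residuals.get(sid, 0.0), floor=-snapshot.counts[sid])
        if d != 0:
            deltas[sid] = d
        if r != 0.0:
            residuals[sid] = r
        else:
            residuals.pop(sid, None)

    request = ChangeRequest(submodel_id=submodel.id, deltas=deltas)
    return request, OdeCarry(residuals)
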