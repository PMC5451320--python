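"""Gillespie direct-method engine.

Integrates a mass-action submodel exactly over one controller step and
reports the net species changes as a :class:`~wcsim.state.ChangeRequest`.

Propensity convention
---------------------
For a reaction with stochastic constant ``c`` and reactant stoichiometries
``s_i`` over counts ``n_i``::

    a = c * prod_i C(n_i, s_i)

i.e. ``c`` times the number of distinct reactant *combinations* (binomial
coefficients, not falling factorials).  Rate constants taken from a
permutation convention (``n_i!/(n_i-s_i)!`` factors) must be multiplied by
``prod_i s_i!`` before use.  A reaction with no reactants (a source) has
propensity ``c``.  Disabled reactions and reactions lacking sufficient
copies have propensity zero.

The engine works on a private copy of the snapshot counts; events whose
firing time would exceed the step end are discarded (integrate-to-barrier),
so every request is attributable to ``[t, t + dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import Reaction, Submodel
from .state import ChangeRequest, EngineNumericError, StateCorruptionError, StateSnapshot


@dataclass
class SsaResult:
    """Outcome of one stochastic step: the request plus event bookkeeping."""

    request: ChangeRequest
    n_events: int
    final_local_time: float


def propensity(
    reaction: Reaction,
    counts,
    parameters=None,
    enabled: bool | None = None,
) -> float:
    """Mass-action propensity of ``reaction`` given integer ``counts``.

    ``parameters`` (optional mapping) resolves ``rate_parameter`` overrides;
    ``enabled`` overrides the reaction's own flag (used by the controller to
    apply Boolean-rule enablement without mutating the model).

    Raises
    ------
    StateCorruptionError
        If any reactant count is negative.
    EngineNumericError
        If the propensity overflows to a non-finite value.
    """
    if enabled is None:
        enabled = reaction.enabled
    if not enabled:
        return 0.0
    c = reaction.rate_constant
    if reaction.rate_parameter is not None and parameters and reaction.rate_parameter in parameters:
        c = float(parameters[reaction.rate_parameter])
    a = float(c)
    for sid, s in reaction.reactants.items():
        n = counts[sid]
        if n < 0:
            raise StateCorruptionError(
                f"negative count {n} for reactant '{sid}' of reaction '{reaction.id}'"
            )
        if n < s:
            return 0.0
        a *= math.comb(n, s)
    if not math.isfinite(a):
        raise EngineNumericError(f"propensity overflow in reaction '{reaction.id}'")
    return a


def ssa_advance(
    snapshot: StateSnapshot,
    submodel: Submodel,
    dt: float,
    rng: np.random.Generator,
) -> SsaResult:
    """Run the direct method over ``[0, dt)`` from ``snapshot``.

    Exponential waiting times between events; reaction choice proportional to
    propensity.  The snapshot is never modified: events update a private copy
    of the counts.  Identical ``(snapshot, dt, rng state)`` always yields an
    identical result.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    reactions = submodel.reactions
    counts = {sid: snapshot.counts[sid] for sid in submodel.interface_species}
    enabled = [snapshot.is_enabled(r) for r in reactions]
    params = snapshot.parameters

    deltas: dict[str, int] = {}
    t = 0.0
    n_events = 0
    props = np.empty(len(reactions))
    while True:
        for j, rxn in enumerate(reactions):
            props[j] = propensity(rxn, counts, params, enabled[j])
        a0 = float(props.sum())
        if a0 <= 0.0:
            break
        tau = rng.exponential(1.0 / a0)
        if t + tau > dt:
            break  # the straddling event is discarded
        t += tau
        # propensity-proportional choice by cumulative sum
        u = rng.random() * a0
        j = int(np.searchsorted(np.cumsum(props), u, side="right"))
        j = min(j, len(reactions) - 1)
        rxn = reactions[j]
        for sid, v in rxn.net_stoichiometry().items():
            counts[sid] += v
            deltas[sid] = deltas.get(sid, 0) + v
        n_events += 1

    request = ChangeRequest(
        submodel_id=submodel.id,
        deltas={sid: v for sid, v in deltas.items() if v != 0},
        diagnostics={"n_events": n_events},
    )
    return SsaResult(request=request, n_events=n_events, final_local_time=t)
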