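"""Shared simulation state containers.

These types define the contract between the controller and the formalism
engines.  :class:`StateSnapshot` is the "arrow of time" device: within one
controller step every submodel is integrated from the *same* immutable
snapshot, so no submodel ever observes another's uncommitted output.
:class:`ChangeRequest` carries a submodel's proposed integer species deltas
for the step; the controller arbitrates all requests before anything is
committed to the global pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping


class StateCorruptionError(RuntimeError):
    """A negative molecule count reached an engine — the pool is corrupt."""


class EngineNumericError(RuntimeError):
    """Non-finite quantity produced during integration."""


@dataclass(frozen=True)
class StateSnapshot:
    """Immutable view of the global state at the start of a step.

    ``counts`` maps global species ids to non-negative integer copy numbers.
    ``parameters`` holds the current values of named model parameters.
    ``reaction_enabled`` carries Boolean-rule enablement overrides; a
    reaction absent from the map uses its own ``enabled`` flag.
    """

    time: float
    counts: Mapping[str, int]
    parameters: Mapping[str, float] = field(default_factory=dict)
    reaction_enabled: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # freeze the mappings so engines cannot write through the snapshot
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))
        object.__setattr__(self, "parameters", MappingProxyType(dict(self.parameters)))
        object.__setattr__(
            self, "reaction_enabled", MappingProxyType(dict(self.reaction_enabled))
        )
        for sid, n in self.counts.items():
            if n < 0:
                raise StateCorruptionError(f"negative count {n} for species '{sid}'")

    def is_enabled(self, reaction) -> bool:
        return bool(self.reaction_enabled.get(reaction.id, reaction.enabled))

    def rate_of(self, reaction) -> float:
        """Effective stochastic rate constant, honoring parameter overrides."""
        if reaction.rate_parameter is not None and reaction.rate_parameter in self.parameters:
            return float(self.parameters[reaction.rate_parameter])
        return float(reaction.rate_constant)


@dataclass
class ChangeRequest:
    """A submodel's proposed species deltas for one step.

    Negative deltas are consumption.  Keys are restricted to the submodel's
    interface species.  ``diagnostics`` carries engine bookkeeping (event
    counts, infeasibility flags) for the trajectory log.
    """

    submodel_id: str
    deltas: dict[str, int] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def consumption(self, species_id: str) -> int:
        """Requested consumption of ``species_id`` (non-negative)."""
        return max(0, -self.deltas.get(species_id, 0))

    def production(self, species_id: str) -> int:
        return max(0, self.deltas.get(species_id, 0))
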