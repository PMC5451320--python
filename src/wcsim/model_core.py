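"""Domain types for multi-algorithm whole-cell models.

A whole-cell model is composed of *submodels*, each describing one pathway in
one mathematical formalism (stochastic simulation, deterministic ODEs, flux
balance analysis, or Boolean regulatory rules).  All submodels exchange
material through a single global pool of integer molecule counts.  The types
here capture that composition: compartments, species, irreversible
mass-action reactions, formalism-tagged submodels, and the composed
:class:`WCModel` whose global species set is the union of all submodel
species under an explicit local-to-global identity mapping.

State is integer molecule counts, never concentrations; engines that work in
continuous quantities convert internally.  Reversible reactions are split
into two irreversible halves at load time, since the stochastic engine
requires irreversibility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence


class CompositionError(ValueError):
    """Raised when submodels cannot be merged into a consistent global model."""


class Formalism(str, enum.Enum):
    """Mathematical formalism of a submodel."""

    SSA = "SSA"
    ODE = "ODE"
    FBA = "FBA"
    BOOLEAN = "BOOLEAN"


@dataclass(frozen=True)
class Compartment:
    """A well-mixed physical compartment.

    Parameters
    ----------
    id : str
        Unique identifier within a model.
    name : str
        Human-readable label.
    volume : float
        Compartment volume in liters; must be positive.
    """

    id: str
    name: str = ""
    volume: float = 1.0


@dataclass(frozen=True)
class Species:
    """A molecular species located in one compartment.

    ``initial_count`` is a copy number (molecules), not a concentration.
    ``boundary`` marks species that an FBA submodel exchanges with the global
    pool (they are exempt from the steady-state constraint).
    ``cross_refs`` holds opaque external identifiers (e.g. ChEBI) and is
    never interpreted.
    """

    id: str
    compartment: str
    name: str = ""
    initial_count: int = 0
    boundary: bool = False
    cross_refs: tuple[str, ...] = ()


@dataclass
class Reaction:
    """An irreversible reaction with stochastic mass-action kinetics.

    ``rate_constant`` is the stochastic constant ``c`` in the
    combinatorial-count propensity convention (see :mod:`wcsim.engine_ssa`).
    If ``rate_parameter`` names a model parameter, the parameter's current
    value overrides ``rate_constant`` at evaluation time; this is the hook
    Boolean rules use to throttle kinetics.  ``enabled`` may likewise be
    toggled by Boolean rules via the controller.
    """

    id: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    rate_constant: float = 0.0
    rate_parameter: str | None = None
    enabled: bool = True

    def net_stoichiometry(self) -> dict[str, int]:
        """Net change per firing, products minus reactants."""
        net: dict[str, int] = {}
        for sid, s in self.products.items():
            net[sid] = net.get(sid, 0) + s
        for sid, s in self.reactants.items():
            net[sid] = net.get(sid, 0) - s
        return {sid: v for sid, v in net.items() if v != 0}

    def species_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)


@dataclass
class FbaSpec:
    """Flux bounds and objective of an FBA submodel.

    Bounds and objective coefficients are keyed by reaction id.  Fluxes are
    in molecules per second, matching the integer pool (not mmol/gDW/h; see
    docs for converting standard FBC models).  Missing bounds default to
    ``[0, +inf)``.
    """

    lower_bounds: dict[str, float] = field(default_factory=dict)
    upper_bounds: dict[str, float] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)


@dataclass
class Submodel:
    """A pathway model in a single formalism.

    The payload depends on the formalism: SSA and ODE submodels carry
    ``reactions``; FBA submodels carry ``reactions`` plus an :class:`FbaSpec`;
    Boolean submodels carry ``rules`` (see :mod:`wcsim.engine_boolean`).
    ``species`` and ``compartments`` describe the submodel standalone (as in
    its SBML file); after composition all ids are global.
    ``interface_species`` is the set of global species the submodel reads or
    writes.
    """

    id: str
    formalism: Formalism
    species: list[Species] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    fba: FbaSpec | None = None
    rules: list = field(default_factory=list)  # list[BooleanRule]
    interface_species: set[str] = field(default_factory=set)

    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}


@dataclass
class WCModel:
    """A composed whole-cell model: the union of its submodels' species."""

    compartments: dict[str, Compartment] = field(default_factory=dict)
    global_species: dict[str, Species] = field(default_factory=dict)
    submodels: list[Submodel] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)

    def initial_counts(self) -> dict[str, int]:
        return {sid: sp.initial_count for sid, sp in self.global_species.items()}


@dataclass(frozen=True)
class ValidationIssue:
    """A single validation finding: which element broke which rule."""

    element_id: str
    rule: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if not self.issues:
            return "model valid"
        return "\n".join(
            f"[{i.severity}] {i.rule}: {i.element_id}: {i.message}" for i in self.issues
        )


def validate_model(model: WCModel) -> ValidationReport:
    """Check every structural invariant of a composed model.

    Pure and idempotent: the model is not modified and repeated calls return
    identical reports.  All violations are collected (the report carries
    failures; nothing raises).
    """
    issues: list[ValidationIssue] = []

    def err(element: str, rule: str, msg: str) -> None:
        issues.append(ValidationIssue(element, rule, msg))

    for cid, comp in model.compartments.items():
        if comp.volume <= 0:
            err(cid, "compartment-volume-positive", f"volume {comp.volume} is not > 0")
        if comp.id != cid:
            err(cid, "compartment-key-id", "mapping key does not match compartment id")

    for sid, sp in model.global_species.items():
        if sp.id != sid:
            err(sid, "species-key-id", "mapping key does not match species id")
        if sp.initial_count < 0:
            err(
                sid,
                "species-count-nonnegative",
                f"initial_count {sp.initial_count} violates non-negativity",
            )
        if sp.compartment not in model.compartments:
            err(sid, "species-compartment-exists", f"unknown compartment '{sp.compartment}'")

    seen_rxn: set[str] = set()
    for sm in model.submodels:
        if sm.formalism in (Formalism.SSA, Formalism.ODE) and not sm.reactions:
            issues.append(
                ValidationIssue(
                    sm.id, "submodel-payload", "no reactions in kinetic submodel", "warning"
                )
            )
        if sm.formalism is Formalism.FBA and sm.fba is None:
            err(sm.id, "submodel-payload", "FBA submodel missing bounds/objective spec")
        if sm.formalism is Formalism.BOOLEAN and not sm.rules:
            issues.append(
                ValidationIssue(sm.id, "submodel-payload", "Boolean submodel has no rules", "warning")
            )
        for gid in sm.interface_species:
            if gid not in model.global_species:
                err(sm.id, "interface-species-exist", f"interface species '{gid}' is not global")
        for rxn in sm.reactions:
            if rxn.id in seen_rxn:
                err(rxn.id, "reaction-id-unique", f"duplicate reaction id in submodel '{sm.id}'")
            seen_rxn.add(rxn.id)
            if rxn.rate_constant < 0:
                err(rxn.id, "rate-constant-nonnegative", f"c = {rxn.rate_constant} < 0")
            for role, stoich in (("reactant", rxn.reactants), ("product", rxn.products)):
                for spid, s in stoich.items():
                    if spid not in model.global_species:
                        err(
                            rxn.id,
                            "reaction-species-exist",
                            f"{role} '{spid}' is not a global species",
                        )
                    if not isinstance(s, int) or s <= 0:
                        err(
                            rxn.id,
                            "stoichiometry-positive-integer",
                            f"{role} '{spid}' has stoichiometry {s}",
                        )
        if sm.fba is not None:
            rxn_ids = {r.id for r in sm.reactions}
            for rid in set(sm.fba.lower_bounds) & set(sm.fba.upper_bounds):
                if sm.fba.lower_bounds[rid] > sm.fba.upper_bounds[rid]:
                    err(
                        rid,
                        "fba-bounds-ordered",
                        f"lower bound {sm.fba.lower_bounds[rid]} > upper bound "
                        f"{sm.fba.upper_bounds[rid]}",
                    )
            for rid in set(sm.fba.lower_bounds) | set(sm.fba.upper_bounds) | set(sm.fba.objective):
                if rid not in rxn_ids:
                    err(rid, "fba-reaction-exists", f"bound/objective references unknown reaction")
        for rule in sm.rules:
            for ident in getattr(rule, "referenced_identifiers", lambda: set())():
                if ident not in model.global_species and ident not in model.parameters:
                    err(
                        rule.id,
                        "rule-identifier-exists",
                        f"condition references unknown identifier '{ident}'",
                    )
            eff = getattr(rule, "effect", None)
            if eff is not None and eff.kind == "parameter" and eff.target not in model.parameters:
                err(rule.id, "rule-target-exists", f"unknown parameter '{eff.target}'")
            if eff is not None and eff.kind == "reaction" and eff.target not in seen_rxn:
                err(rule.id, "rule-target-exists", f"unknown reaction '{eff.target}'")

    return ValidationReport(issues)


def split_reversible(
    reaction_id: str,
    reactants: Mapping[str, int],
    products: Mapping[str, int],
    c_forward: float,
    c_backward: float,
    rate_parameter_forward: str | None = None,
    rate_parameter_backward: str | None = None,
) -> tuple[Reaction, Reaction]:
    """Split a reversible mass-action reaction into two irreversible halves.

    The forward half keeps the original reactants/products with constant
    ``c_forward``; the backward half swaps them with ``c_backward``.  Ids are
    suffixed ``_fwd`` / ``_rev``.  The species set is preserved.
    """
    fwd = Reaction(
        id=f"{reaction_id}_fwd",
        reactants=dict(reactants),
        products=dict(products),
        rate_constant=c_forward,
        rate_parameter=rate_parameter_forward,
    )
    rev = Reaction(
        id=f"{reaction_id}_rev",
        reactants=dict(products),
        products=dict(reactants),
        rate_constant=c_backward,
        rate_parameter=rate_parameter_backward,
    )
    return fwd, rev


def _rename_reaction(rxn: Reaction, local_to_global: Mapping[str, str]) -> Reaction:
    return replace(
        rxn,
        reactants={local_to_global[s]: v for s, v in rxn.reactants.items()},
        products={local_to_global[s]: v for s, v in rxn.products.items()},
    )


def merge_shared_species(
    submodels: Sequence[Submodel],
    mapping: Mapping[tuple[str, str], str],
    *,
    initial_counts: Mapping[str, int] | None = None,
    parameters: Mapping[str, float] | None = None,
) -> WCModel:
    """Compose submodels into a :class:`WCModel` under an explicit species map.

    ``mapping`` sends each ``(submodel_id, local_species_id)`` pair to a
    global species id; the global species set is the union of the images.
    The map must be total (every local species covered) and
    compartment-consistent (two locals mapped to one global id must live in
    the same compartment).  Initial counts come from ``initial_counts`` (the
    composition manifest); for species the manifest omits, the local values
    are used when all declaring submodels agree, otherwise composition fails.

    Raises
    ------
    CompositionError
        On unmapped species or compartment conflicts.
    """
    initial_counts = dict(initial_counts or {})
    compartments: dict[str, Compartment] = {}
    global_species: dict[str, Species] = {}
    local_counts: dict[str, dict[str, int]] = {}
    merged: list[Submodel] = []

    for sm in submodels:
        for comp in sm.compartments:
            if comp.id in compartments and compartments[comp.id].volume != comp.volume:
                raise CompositionError(
                    f"compartment '{comp.id}' declared with conflicting volumes "
                    f"{compartments[comp.id].volume} and {comp.volume}"
                )
            compartments.setdefault(comp.id, comp)

        local_to_global: dict[str, str] = {}
        for sp in sm.species:
            key = (sm.id, sp.id)
            if key not in mapping:
                raise CompositionError(
                    f"species '{sp.id}' of submodel '{sm.id}' has no global mapping"
                )
            gid = mapping[key]
            local_to_global[sp.id] = gid
            if gid in global_species:
                existing = global_species[gid]
                if existing.compartment != sp.compartment:
                    raise CompositionError(
                        f"global species '{gid}' placed in compartment "
                        f"'{existing.compartment}' by one submodel and "
                        f"'{sp.compartment}' by submodel '{sm.id}'"
                    )
                if sp.boundary and not existing.boundary:
                    global_species[gid] = replace(existing, boundary=True)
            else:
                global_species[gid] = replace(sp, id=gid, initial_count=0)
            local_counts.setdefault(gid, {})[sm.id] = sp.initial_count

        merged.append(
            replace(
                sm,
                species=[global_species[local_to_global[sp.id]] for sp in sm.species],
                reactions=[_rename_reaction(r, local_to_global) for r in sm.reactions],
                interface_species=set(local_to_global.values()),
            )
        )

    for gid in initial_counts:
        if gid not in global_species:
            raise CompositionError(
                f"manifest sets initial count for '{gid}', which no submodel declares"
            )

    for gid, sp in global_species.items():
        if gid in initial_counts:
            count = int(initial_counts[gid])
        else:
            locals_ = set(local_counts[gid].values())
            if len(locals_) > 1:
                raise CompositionError(
                    f"species '{gid}' has conflicting local initial counts "
                    f"{sorted(local_counts[gid].items())}; set it in the manifest"
                )
            count = locals_.pop()
        global_species[gid] = replace(sp, initial_count=count)

    # merged submodels share the finalized Species objects
    for sm in merged:
        sm.species = [global_species[sp.id] for sp in sm.species]

    return WCModel(
        compartments=compartments,
        global_species=global_species,
        submodels=merged,
        parameters=dict(parameters or {}),
    )
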