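"""SBML, manifest, and trajectory I/O.

Submodels are stored one per file in an SBML Level 3 Version 1 core subset:
compartments, species with integer initial amounts
(``hasOnlySubstanceUnits`` semantics — amounts are molecule counts, never
concentrations), and irreversible mass-action reactions whose kinetic law is
a constant times the product of reactant species.  FBA submodels use the
Flux Balance Constraints (FBC) idiom: bounds as parameters referenced from
reactions, an active maximization objective, and ``boundaryCondition`` on
pool-coupled species.  Anything outside this subset (events, rules,
constraints, initial assignments, function definitions, non-mass-action
kinetics) is rejected loudly, never silently ignored.

Composition is expressed by an explicit JSON/YAML *manifest* rather than the
SBML hierarchical composition package: each submodel entry carries a file
path, a formalism tag, and a total local→global species map; the manifest
also holds global initial counts (which override the per-file values),
model parameters, and Boolean rules.  Every submodel file remains valid
standalone SBML.

Trajectories persist to CSV (header ``time`` + species ids) or HDF5
(``/times``, ``/counts``, ``/species_ids``, ``/diagnostics``), with lossless
integer counts.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import libsbml
import numpy as np
import yaml

from . import engine_boolean
from .controller import Trajectory
from .model_core import (
    Compartment,
    FbaSpec,
    Formalism,
    Reaction,
    Species,
    Submodel,
    WCModel,
    merge_shared_species,
    split_reversible,
    validate_model,
)


class SbmlIoError(ValueError):
    pass


class UnsupportedConstructError(SbmlIoError):
    """The document uses an SBML construct outside the supported subset."""


class MassActionParseError(SbmlIoError):
    """A kinetic law is not of mass-action form c · ∏ reactants."""


class ManifestError(SbmlIoError):
    pass


_FORMALISM_ANNOTATION = re.compile(r"wcsim:formalism[^>]*>\s*([A-Z]+)\s*<")
_WCSIM_NS = "https://github.com/wcsim/wcsim"


# ---------------------------------------------------------------------------
# writing


def _check(obj, what: str):
    if obj is None or (isinstance(obj, int) and obj != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise SbmlIoError(f"libsbml operation failed: {what}")
    return obj


def submodel_to_sbml(submodel: Submodel) -> libsbml.SBMLDocument:
    """Encode a submodel as a standalone SBML document."""
    use_fbc = submodel.formalism is Formalism.FBA
    if use_fbc:
        ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
        doc = libsbml.SBMLDocument(ns)
        doc.setPackageRequired("fbc", False)
    else:
        doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(submodel.id)
    model.appendAnnotation(
        f'<wcsim:formalism xmlns:wcsim="{_WCSIM_NS}">{submodel.formalism.value}</wcsim:formalism>'
    )

    for comp in submodel.compartments:
        c = model.createCompartment()
        c.setId(comp.id)
        if comp.name:
            c.setName(comp.name)
        c.setSize(comp.volume)
        c.setSpatialDimensions(3)
        c.setConstant(True)

    for sp in submodel.species:
        s = model.createSpecies()
        s.setId(sp.id)
        if sp.name:
            s.setName(sp.name)
        s.setCompartment(sp.compartment)
        s.setInitialAmount(float(sp.initial_count))
        s.setHasOnlySubstanceUnits(True)
        s.setBoundaryCondition(bool(sp.boundary))
        s.setConstant(False)
        for ref in sp.cross_refs:
            cv = libsbml.CVTerm(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            cv.addResource(ref)
            s.setMetaId(f"meta_{sp.id}")
            s.addCVTerm(cv)

    for rxn in submodel.reactions:
        pname = rxn.rate_parameter or f"k_{rxn.id}"
        if model.getParameter(pname) is None:
            p = model.createParameter()
            p.setId(pname)
            p.setValue(float(rxn.rate_constant))
            p.setConstant(rxn.rate_parameter is None)
        r = model.createReaction()
        r.setId(rxn.id)
        r.setReversible(False)
        r.setFast(False)
        for sid, stoich in rxn.reactants.items():
            sr = r.createReactant()
            sr.setSpecies(sid)
            sr.setStoichiometry(float(stoich))
            sr.setConstant(True)
        for sid, stoich in rxn.products.items():
            sr = r.createProduct()
            sr.setSpecies(sid)
            sr.setStoichiometry(float(stoich))
            sr.setConstant(True)
        if not use_fbc:
            factors = [pname] + [
                sid for sid, stoich in sorted(rxn.reactants.items()) for _ in range(stoich)
            ]
            math = libsbml.parseL3Formula(" * ".join(factors))
            _check(math, f"kinetic law of '{rxn.id}'")
            kl = r.createKineticLaw()
            kl.setMath(math)

    if use_fbc:
        spec = submodel.fba or FbaSpec()
        mplug = model.getPlugin("fbc")
        mplug.setStrict(False)
        for rxn in submodel.reactions:
            rplug = model.getReaction(rxn.id).getPlugin("fbc")
            for prefix, table in (("lb", spec.lower_bounds), ("ub", spec.upper_bounds)):
                if rxn.id in table:
                    pid = f"{prefix}_{rxn.id}"
                    p = model.createParameter()
                    p.setId(pid)
                    p.setValue(float(table[rxn.id]))
                    p.setConstant(True)
                    if prefix == "lb":
                        rplug.setLowerFluxBound(pid)
                    else:
                        rplug.setUpperFluxBound(pid)
        if spec.objective:
            obj = mplug.createObjective()
            obj.setId("obj")
            obj.setType("maximize")
            for rid, coeff in sorted(spec.objective.items()):
                fo = obj.createFluxObjective()
                fo.setReaction(rid)
                fo.setCoefficient(float(coeff))
            mplug.setActiveObjectiveId("obj")

    return doc


def write_submodel_sbml(submodel: Submodel, path: str | Path | None = None) -> str:
    """Serialize a submodel; returns the XML text (and writes ``path`` if given).

    Round-trip contract: ``read_submodel_sbml(write_submodel_sbml(s))``
    reproduces ``s`` exactly (ids, stoichiometries, constants, bounds,
    objective).
    """
    doc = submodel_to_sbml(submodel)
    xml = libsbml.writeSBMLToString(doc)
    if path is not None:
        Path(path).write_text(xml)
    return xml


# ---------------------------------------------------------------------------
# reading


def _flatten_times(node) -> list:
    if node.getType() == libsbml.AST_TIMES:
        out = []
        for i in range(node.getNumChildren()):
            out.extend(_flatten_times(node.getChild(i)))
        return out
    return [node]


def _parse_mass_action_term(node, model, rxn, formula: str) -> tuple[float, str | None]:
    """Return (c, rate_parameter) for one mass-action product term."""
    const = 1.0
    param_name = None
    param_value = None
    reactant_pool = dict(
        (rxn.getReactant(i).getSpecies(), int(round(rxn.getReactant(i).getStoichiometry())))
        for i in range(rxn.getNumReactants())
    )
    for factor in _flatten_times(node):
        t = factor.getType()
        if t in (libsbml.AST_REAL, libsbml.AST_INTEGER, libsbml.AST_RATIONAL, libsbml.AST_REAL_E):
            const *= factor.getValue()
        elif t == libsbml.AST_NAME:
            name = factor.getName()
            if name in reactant_pool and reactant_pool[name] > 0:
                reactant_pool[name] -= 1
            elif model.getParameter(name) is not None:
                if param_name is not None:
                    raise MassActionParseError(
                        f"reaction '{rxn.getId()}': more than one parameter in '{formula}'"
                    )
                param_name = name
                param_value = model.getParameter(name).getValue()
            else:
                raise MassActionParseError(
                    f"reaction '{rxn.getId()}': factor '{name}' is neither a reactant "
                    f"nor a parameter in '{formula}'"
                )
        elif t in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
            base, exp = factor.getChild(0), factor.getChild(1)
            if base.getType() != libsbml.AST_NAME or not exp.isNumber():
                raise MassActionParseError(
                    f"reaction '{rxn.getId()}': non-mass-action power in '{formula}'"
                )
            name, e = base.getName(), int(exp.getValue())
            if name not in reactant_pool or reactant_pool[name] < e:
                raise MassActionParseError(
                    f"reaction '{rxn.getId()}': power of non-reactant '{name}' in '{formula}'"
                )
            reactant_pool[name] -= e
        else:
            raise MassActionParseError(
                f"reaction '{rxn.getId()}': unsupported kinetic law '{formula}'"
            )
    if param_name is None:
        return const, None
    return const * param_value, param_name


def _reject_unsupported(model) -> None:
    if model.getNumRules() > 0:
        rule = model.getRule(0)
        raise UnsupportedConstructError(
            f"rule on '{rule.getVariable() or rule.getId() or 'anonymous'}' is outside the subset"
        )
    if model.getNumEvents() > 0:
        raise UnsupportedConstructError(
            f"event '{model.getEvent(0).getId() or 'anonymous'}' is outside the subset"
        )
    if model.getNumConstraints() > 0:
        raise UnsupportedConstructError("constraint elements are outside the subset")
    if model.getNumInitialAssignments() > 0:
        ia = model.getInitialAssignment(0)
        raise UnsupportedConstructError(
            f"initial assignment on '{ia.getSymbol()}' is outside the subset"
        )
    if model.getNumFunctionDefinitions() > 0:
        fd = model.getFunctionDefinition(0)
        raise UnsupportedConstructError(
            f"function definition '{fd.getId()}' is outside the subset"
        )


def read_submodel_sbml(
    source: str | Path, formalism: Formalism | str | None = None
) -> Submodel:
    """Load a submodel from SBML text or a file path.

    Kinetic laws must be mass-action (one rate parameter times reactant
    species); reversible reactions must have a ``kf·∏reactants −
    kr·∏products`` law and are split into ``_fwd``/``_rev`` halves.  The
    formalism is taken from the ``formalism`` argument if given, else from
    the document's annotation, defaulting to SSA.
    """
    text = str(source)
    if "<" not in text and Path(text).exists():
        text = Path(text).read_text()
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SbmlIoError(doc.getErrorLog().toString())
    model = doc.getModel()
    if model is None:
        raise SbmlIoError("document contains no model")
    _reject_unsupported(model)

    if formalism is None:
        ann = model.getAnnotationString() or ""
        m = _FORMALISM_ANNOTATION.search(ann)
        formalism = Formalism(m.group(1)) if m else Formalism.SSA
    formalism = Formalism(formalism)

    compartments = [
        Compartment(
            id=model.getCompartment(i).getId(),
            name=model.getCompartment(i).getName() or "",
            volume=model.getCompartment(i).getSize()
            if model.getCompartment(i).isSetSize()
            else 1.0,
        )
        for i in range(model.getNumCompartments())
    ]
    species = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        refs = tuple(
            s.getCVTerm(k).getResourceURI(j)
            for k in range(s.getNumCVTerms())
            for j in range(s.getCVTerm(k).getNumResources())
        )
        species.append(
            Species(
                id=s.getId(),
                compartment=s.getCompartment(),
                name=s.getName() or "",
                initial_count=int(round(s.getInitialAmount())) if s.isSetInitialAmount() else 0,
                boundary=bool(s.getBoundaryCondition()),
                cross_refs=refs,
            )
        )

    reactions: list[Reaction] = []
    fba = FbaSpec() if formalism is Formalism.FBA else None
    if fba is not None:
        mplug = model.getPlugin("fbc")
        if mplug is not None and mplug.getNumObjectives() > 0:
            obj = mplug.getActiveObjective() or mplug.getObjective(0)
            for k in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(k)
                fba.objective[fo.getReaction()] = fo.getCoefficient()
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        reactants = {
            r.getReactant(j).getSpecies(): int(round(r.getReactant(j).getStoichiometry()))
            for j in range(r.getNumReactants())
        }
        products = {
            r.getProduct(j).getSpecies(): int(round(r.getProduct(j).getStoichiometry()))
            for j in range(r.getNumProducts())
        }

        if formalism is Formalism.FBA:
            rplug = r.getPlugin("fbc")
            if rplug is not None:
                for getter, table in (
                    (rplug.getLowerFluxBound, fba.lower_bounds),
                    (rplug.getUpperFluxBound, fba.upper_bounds),
                ):
                    pid = getter()
                    if pid:
                        p = model.getParameter(pid)
                        if p is None:
                            raise SbmlIoError(
                                f"reaction '{r.getId()}' references missing bound parameter '{pid}'"
                            )
                        table[r.getId()] = p.getValue()
            reactions.append(Reaction(id=r.getId(), reactants=reactants, products=products))
            continue

        kl = r.getKineticLaw()
        if kl is None or kl.getMath() is None:
            raise MassActionParseError(f"reaction '{r.getId()}' has no kinetic law")
        math = kl.getMath()
        formula = libsbml.formulaToL3String(math)
        if r.getReversible():
            if math.getType() != libsbml.AST_MINUS or math.getNumChildren() != 2:
                raise MassActionParseError(
                    f"reversible reaction '{r.getId()}' needs a kf·∏ − kr·∏ law, got '{formula}'"
                )
            cf, pf = _parse_mass_action_term(math.getChild(0), model, r, formula)
            # backward term: reactants/products swap roles; reuse the parser on a
            # mirrored reaction view
            mirrored = r.clone()
            while mirrored.getNumReactants():
                mirrored.removeReactant(0)
            for sid, stoich in products.items():
                sr = mirrored.createReactant()
                sr.setSpecies(sid)
                sr.setStoichiometry(float(stoich))
            cb, pb = _parse_mass_action_term(math.getChild(1), model, mirrored, formula)
            fwd, rev = split_reversible(r.getId(), reactants, products, cf, cb, pf, pb)
            if pf == f"k_{r.getId()}":
                fwd.rate_parameter = None
            reactions.extend([fwd, rev])
        else:
            c, pname = _parse_mass_action_term(math, model, r, formula)
            # an auto-named constant parameter (k_<reaction id>, constant="true")
            # is an inlined rate constant; anything else is a live reference
            auto = (
                pname is None
                or (pname == f"k_{r.getId()}" and model.getParameter(pname).getConstant())
            )
            reactions.append(
                Reaction(
                    id=r.getId(),
                    reactants=reactants,
                    products=products,
                    rate_constant=c,
                    rate_parameter=None if auto else pname,
                )
            )

    sm = Submodel(
        id=model.getId() or "submodel",
        formalism=formalism,
        species=species,
        compartments=compartments,
        reactions=reactions,
        fba=fba,
        interface_species={sp.id for sp in species},
    )
    return sm


# ---------------------------------------------------------------------------
# manifests


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_manifest(path: str | Path):
    """Compose a :class:`WCModel` from a manifest and its submodel files.

    Returns ``(model, manifest_dict)``.  The composed model is validated;
    composition failures (missing files, unmapped species, compartment
    conflicts, unknown formalisms) raise with the offending location named.
    """
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, dict) or "submodels" not in data:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'submodels' list")

    submodels: list[Submodel] = []
    boolean_submodels: list[Submodel] = []
    mapping: dict[tuple[str, str], str] = {}
    for entry in data["submodels"]:
        smid = entry.get("id")
        if smid is None:
            raise ManifestError(f"{path}: submodel entry without id: {entry}")
        try:
            formalism = Formalism(entry.get("formalism"))
        except ValueError:
            raise ManifestError(
                f"{path}: submodel '{smid}' has unknown formalism "
                f"{entry.get('formalism')!r} (must be one of "
                f"{[f.value for f in Formalism]})"
            ) from None
        if formalism is Formalism.BOOLEAN:
            rules = engine_boolean.rules_from_dicts(entry.get("rules", []))
            boolean_submodels.append(Submodel(id=smid, formalism=formalism, rules=rules))
            continue
        file = entry.get("file")
        if file is None:
            raise ManifestError(f"{path}: submodel '{smid}' has no file")
        file_path = (path.parent / file).resolve()
        if not file_path.exists():
            raise ManifestError(f"{path}: submodel '{smid}' file not found: {file_path}")
        sm = read_submodel_sbml(file_path, formalism)
        sm.id = smid
        species_map = entry.get("species_map", {})
        for sp in sm.species:
            mapping[(smid, sp.id)] = species_map.get(sp.id, sp.id)
        submodels.append(sm)

    if "boolean_rules" in data:
        boolean_submodels.append(
            Submodel(
                id="boolean_rules",
                formalism=Formalism.BOOLEAN,
                rules=engine_boolean.rules_from_dicts(data["boolean_rules"]),
            )
        )

    model = merge_shared_species(
        submodels,
        mapping,
        initial_counts=data.get("global_initial_counts"),
        parameters=data.get("parameters"),
    )
    for bsm in boolean_submodels:
        bsm.interface_species = {
            ident
            for rule in bsm.rules
            for ident in rule.referenced_identifiers()
            if ident in model.global_species
        }
        model.submodels.append(bsm)

    report = validate_model(model)
    if not report.ok:
        raise ManifestError(f"{path}: composed model invalid:\n{report}")
    return model, data


def write_model(model: WCModel, out_dir: str | Path, manifest_name: str = "manifest.yaml") -> Path:
    """Write a composed model as per-submodel SBML files plus a manifest.

    Species ids are already global in a composed model, so the manifest's
    species maps are identities.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sm in model.submodels:
        if sm.formalism is Formalism.BOOLEAN:
            entries.append(
                {
                    "id": sm.id,
                    "formalism": "BOOLEAN",
                    "rules": engine_boolean.rules_to_dicts(sm.rules),
                }
            )
            continue
        fname = f"{sm.id}.xml"
        write_submodel_sbml(sm, out_dir / fname)
        entries.append(
            {
                "id": sm.id,
                "file": fname,
                "formalism": sm.formalism.value,
                "species_map": {sp.id: sp.id for sp in sm.species},
            }
        )
    manifest = {
        "submodels": entries,
        "global_initial_counts": {
            sid: sp.initial_count for sid, sp in sorted(model.global_species.items())
        },
        "parameters": dict(model.parameters),
    }
    mpath = out_dir / manifest_name
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> Path:
    """Persist a trajectory to CSV or HDF5 (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "csv":
        traj.to_frame().to_csv(path, index=False)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=traj.times)
            f.create_dataset("counts", data=traj.counts, dtype=np.int64)
            f.create_dataset(
                "species_ids", data=np.array(traj.species_ids, dtype=h5py.string_dtype())
            )
            g = f.create_group("diagnostics")
            if traj.diagnostics:
                for key in ("step", "time", "dt", "n_scaled_species", "retries"):
                    g.create_dataset(key, data=np.array([d[key] for d in traj.diagnostics]))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return path


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if format == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        species = [c for c in df.columns if c != "time"]
        return Trajectory(
            species_ids=species,
            times=df["time"].to_numpy(dtype=float),
            counts=df[species].to_numpy(dtype=np.int64),
        )
    with h5py.File(path, "r") as f:
        species = [s.decode() if isinstance(s, bytes) else str(s) for s in f["species_ids"][()]]
        diagnostics = []
        if "diagnostics" in f and "step" in f["diagnostics"]:
            g = f["diagnostics"]
            keys = list(g.keys())
            n = len(g["step"])
            diagnostics = [{k: g[k][i].item() for k in keys} for i in range(n)]
        return Trajectory(
            species_ids=species,
            times=f["times"][()].astype(float),
            counts=f["counts"][()].astype(np.int64),
            diagnostics=diagnostics,
        )
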