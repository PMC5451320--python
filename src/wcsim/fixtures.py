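"""Programmatic example models.

Everything the engines and the controller need for testing and
demonstration is generated here in memory — no downloads, no bundled data
files.  The centerpiece fixtures are:

* a lumped *transcription* submodel: one stochastic reaction per RNA species
  (RNA polymerase + the RNA's NTP composition → polymerase + RNA), with no
  per-base elongation reactions and no explicit DNA–protein binding;
* a *minimal cell*: three compartments (extracellular, membrane, cytosol)
  and four submodels, one per formalism — stochastic transcription,
  deterministic first-order RNA degradation, FBA metabolism replenishing
  NTPs from an extracellular nutrient under a biomass objective, and a
  Boolean rule that switches RNA degradation off when total RNA is low;
* random hybrid models for fuzz testing.

Default kinetic constants are arbitrary, chosen so the ten-second demo stays
in the hundreds-of-molecules regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine_boolean import BooleanRule, Effect
from .model_core import (
    Compartment,
    FbaSpec,
    Formalism,
    Reaction,
    Species,
    Submodel,
    WCModel,
    merge_shared_species,
)

NTP_IDS = ("ATP", "CTP", "GTP", "UTP")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class RnaSpec:
    """One RNA species for the lumped transcription fixture.

    ``composition`` counts (A, C, G, U) nucleotides and must sum to
    ``length``; ``k_txn`` is the stochastic constant of the single lumped
    initiation+elongation+termination reaction.
    """

    id: str
    length: int
    composition: tuple[int, int, int, int]
    k_txn: float

    def __post_init__(self) -> None:
        if sum(self.composition) != self.length:
            raise FixtureError(
                f"RNA '{self.id}': composition {self.composition} does not sum "
                f"to length {self.length}"
            )
        if self.k_txn < 0:
            raise FixtureError(f"RNA '{self.id}': negative k_txn")


def make_transcription_submodel(
    rnas: list[RnaSpec],
    n_rnap: int = 10,
    ntp_counts: dict[str, int] | None = None,
    compartment: str = "c",
) -> Submodel:
    """Lumped stochastic transcription: one reaction per RNA species.

    Each reaction consumes the RNA's NTP composition, is catalyzed by RNA
    polymerase (consumed and re-released), and produces one RNA molecule.
    """
    if n_rnap < 0:
        raise FixtureError("n_rnap must be >= 0")
    ntp_counts = ntp_counts or {f"{n}_{compartment}": 500 for n in NTP_IDS}
    comp = Compartment(id=compartment, name="cytosol", volume=1e-15)
    rnap = f"RNAP_{compartment}"
    species = [Species(id=rnap, compartment=compartment, name="RNA polymerase", initial_count=n_rnap)]
    for n in NTP_IDS:
        sid = f"{n}_{compartment}"
        species.append(
            Species(id=sid, compartment=compartment, name=n, initial_count=ntp_counts.get(sid, 0))
        )
    reactions = []
    for rna in rnas:
        sid = f"{rna.id}_{compartment}"
        species.append(Species(id=sid, compartment=compartment, name=rna.id, initial_count=0))
        reactants = {rnap: 1}
        for n, count in zip(NTP_IDS, rna.composition):
            if count:
                reactants[f"{n}_{compartment}"] = count
        reactions.append(
            Reaction(
                id=f"txn_{rna.id}",
                reactants=reactants,
                products={rnap: 1, sid: 1},
                rate_constant=rna.k_txn,
            )
        )
    return Submodel(
        id="transcription",
        formalism=Formalism.SSA,
        species=species,
        compartments=[comp],
        reactions=reactions,
        interface_species={sp.id for sp in species},
    )


def _snap(x: float) -> float:
    """Round to 15 significant digits — the SBML writer's precision — so
    fixture constants survive a write/read cycle bit-exactly."""
    return float(f"{x:.15g}")


def _lumped_k(target_rate: float, n_rnap: int, ntp0: int, composition) -> float:
    """Stochastic constant giving ``target_rate`` initial propensity."""
    combos = n_rnap
    for s in composition:
        if s:
            combos *= math.comb(ntp0, s)
    return _snap(target_rate / combos) if combos else 0.0


def make_minimal_cell_model() -> tuple[WCModel, dict]:
    """Three-compartment minimal cell with one submodel per formalism.

    Returns the composed model plus its manifest dictionary (the same
    structure :func:`wcsim.io_sbml.read_manifest` consumes, with file names
    as they would be written by ``write_model``).
    """
    n_rnap, ntp0 = 10, 500
    rnas = [
        RnaSpec("RNA_1", 10, (3, 2, 2, 3), _lumped_k(0.5, n_rnap, ntp0, (3, 2, 2, 3))),
        RnaSpec("RNA_2", 8, (2, 2, 2, 2), _lumped_k(0.5, n_rnap, ntp0, (2, 2, 2, 2))),
    ]
    txn = make_transcription_submodel(rnas, n_rnap=n_rnap)

    cytosol = Compartment(id="c", name="cytosol", volume=1e-15)
    membrane = Compartment(id="m", name="membrane", volume=1e-16)
    extracellular = Compartment(id="e", name="extracellular", volume=1e-12)

    deg = Submodel(
        id="degradation",
        formalism=Formalism.ODE,
        compartments=[cytosol],
        species=[
            Species(id="RNA_1_c", compartment="c", initial_count=0),
            Species(id="RNA_2_c", compartment="c", initial_count=0),
        ],
        reactions=[
            Reaction(id="deg_RNA_1", reactants={"RNA_1_c": 1}, rate_parameter="k_deg"),
            Reaction(id="deg_RNA_2", reactants={"RNA_2_c": 1}, rate_parameter="k_deg"),
        ],
    )

    met_species = [
        Species(id="X_e", compartment="e", name="nutrient", initial_count=10000, boundary=True),
        Species(id="T_m", compartment="m", name="transporter", initial_count=1, boundary=True),
        Species(id="P_c", compartment="c", name="precursor", initial_count=0),
        Species(id="BIOMASS_c", compartment="c", name="biomass", initial_count=0, boundary=True),
    ] + [
        Species(id=f"{n}_c", compartment="c", name=n, initial_count=ntp0, boundary=True)
        for n in NTP_IDS
    ]
    met_reactions = [
        Reaction(id="upt", reactants={"X_e": 1, "T_m": 1}, products={"P_c": 1, "T_m": 1})
    ] + [
        Reaction(id=f"syn_{n.lower()}", reactants={"P_c": 1}, products={f"{n}_c": 1})
        for n in NTP_IDS
    ] + [
        Reaction(id="growth", reactants={"P_c": 1}, products={"BIOMASS_c": 1})
    ]
    metabolism = Submodel(
        id="metabolism",
        formalism=Formalism.FBA,
        compartments=[extracellular, membrane, cytosol],
        species=met_species,
        reactions=met_reactions,
        fba=FbaSpec(
            lower_bounds={r.id: 0.0 for r in met_reactions},
            upper_bounds={
                "upt": 21.0,
                **{f"syn_{n.lower()}": 4.0 for n in NTP_IDS},
                "growth": 5.0,
            },
            objective={"growth": 1.0, **{f"syn_{n.lower()}": 0.1 for n in NTP_IDS}},
        ),
    )

    rules = [
        BooleanRule(
            id="halt_degradation",
            condition="RNA_1_c + RNA_2_c < 5",
            effect=Effect(kind="parameter", target="k_deg", value=0.0),
        ),
        BooleanRule(
            id="resume_degradation",
            condition="RNA_1_c + RNA_2_c >= 5",
            effect=Effect(kind="parameter", target="k_deg", value=0.05),
        ),
    ]
    regulation = Submodel(id="regulation", formalism=Formalism.BOOLEAN, rules=rules)

    kinetic = [txn, deg, metabolism]
    mapping = {(sm.id, sp.id): sp.id for sm in kinetic for sp in sm.species}
    counts = {
        "RNAP_c": n_rnap,
        **{f"{n}_c": ntp0 for n in NTP_IDS},
        "RNA_1_c": 0,
        "RNA_2_c": 0,
        "X_e": 10000,
        "T_m": 1,
        "P_c": 0,
        "BIOMASS_c": 0,
    }
    parameters = {"k_deg": 0.05}
    model = merge_shared_species(kinetic, mapping, initial_counts=counts, parameters=parameters)
    regulation.interface_species = {"RNA_1_c", "RNA_2_c"}
    model.submodels.append(regulation)

    from .engine_boolean import rules_to_dicts

    manifest = {
        "submodels": [
            {
                "id": sm.id,
                "file": f"{sm.id}.xml",
                "formalism": sm.formalism.value,
                "species_map": {sp.id: sp.id for sp in sm.species},
            }
            for sm in kinetic
        ]
        + [{"id": "regulation", "formalism": "BOOLEAN", "rules": rules_to_dicts(rules)}],
        "global_initial_counts": counts,
        "parameters": parameters,
    }
    return model, manifest


def make_immigration_death_model(
    birth_rate: float = 10.0, death_rate: float = 0.1, initial: int = 100
) -> WCModel:
    """Immigration–death process ∅→A (rate b), A→∅ (rate d·n).

    Stationary distribution is Poisson with mean and variance ``b/d``.
    """
    sm = Submodel(
        id="birth_death",
        formalism=Formalism.SSA,
        compartments=[Compartment(id="c", volume=1e-15)],
        species=[Species(id="A_c", compartment="c", initial_count=initial)],
        reactions=[
            Reaction(id="birth", products={"A_c": 1}, rate_constant=birth_rate),
            Reaction(id="death", reactants={"A_c": 1}, rate_constant=death_rate),
        ],
    )
    return merge_shared_species([sm], {("birth_death", "A_c"): "A_c"})


def make_conversion_chain_model(
    hybrid: bool, k1: float = 0.1, k2: float = 0.1, a0: int = 500
) -> WCModel:
    """Linear chain A→B→C.

    ``hybrid=True`` splits the chain across two submodels — A→B stochastic,
    B→C deterministic — sharing species B; ``hybrid=False`` puts both
    reactions in one stochastic submodel (the exact reference).
    """
    comp = Compartment(id="c", volume=1e-15)
    sp = {
        "A_c": Species(id="A_c", compartment="c", initial_count=a0),
        "B_c": Species(id="B_c", compartment="c", initial_count=0),
        "C_c": Species(id="C_c", compartment="c", initial_count=0),
    }
    r1 = Reaction(id="conv_ab", reactants={"A_c": 1}, products={"B_c": 1}, rate_constant=k1)
    r2 = Reaction(id="conv_bc", reactants={"B_c": 1}, products={"C_c": 1}, rate_constant=k2)
    if hybrid:
        sm1 = Submodel(
            id="upstream",
            formalism=Formalism.SSA,
            compartments=[comp],
            species=[sp["A_c"], sp["B_c"]],
            reactions=[r1],
        )
        sm2 = Submodel(
            id="downstream",
            formalism=Formalism.ODE,
            compartments=[comp],
            species=[sp["B_c"], sp["C_c"]],
            reactions=[r2],
        )
        mapping = {
            ("upstream", "A_c"): "A_c",
            ("upstream", "B_c"): "B_c",
            ("downstream", "B_c"): "B_c",
            ("downstream", "C_c"): "C_c",
        }
        return merge_shared_species([sm1, sm2], mapping)
    sm = Submodel(
        id="chain",
        formalism=Formalism.SSA,
        compartments=[comp],
        species=list(sp.values()),
        reactions=[r1, r2],
    )
    return merge_shared_species([sm], {("chain", sid): sid for sid in sp})


def make_random_hybrid_model(
    seed: int, n_species: int = 8, n_submodels: int = 3
) -> tuple[WCModel, dict]:
    """Deterministic random hybrid model for fuzz testing.

    Each submodel (alternating SSA/ODE) gets a random slice of the species
    plus species ``S0``, which is therefore shared whenever there are at
    least two submodels.  Reactions are random uni/bimolecular conversions
    with small rate constants.  The same seed always yields the same model.
    """
    if n_species < 2 or n_submodels < 1:
        raise FixtureError("need n_species >= 2 and n_submodels >= 1")
    rng = np.random.default_rng(seed)
    comp = Compartment(id="c", volume=1e-15)
    sids = [f"S{i}_c" for i in range(n_species)]
    counts = {sid: int(rng.integers(20, 120)) for sid in sids}

    submodels = []
    mapping = {}
    for k in range(n_submodels):
        smid = f"sub{k}"
        n_local = int(rng.integers(2, n_species + 1))
        local = {sids[0]} | set(rng.choice(sids, size=n_local, replace=False).tolist())
        local = sorted(local)
        reactions = []
        for j in range(int(rng.integers(1, 4))):
            if len(local) >= 3 and rng.random() < 0.4:
                a, b, c = rng.choice(local, size=3, replace=False)
                reactions.append(
                    Reaction(
                        id=f"r{k}_{j}",
                        reactants={str(a): 1, str(b): 1},
                        products={str(c): 1},
                        rate_constant=_snap(rng.uniform(1e-4, 2e-3)),
                    )
                )
            else:
                a, b = rng.choice(local, size=2, replace=False)
                reactions.append(
                    Reaction(
                        id=f"r{k}_{j}",
                        reactants={str(a): 1},
                        products={str(b): 1},
                        rate_constant=_snap(rng.uniform(0.01, 0.2)),
                    )
                )
        species = [
            Species(id=sid, compartment="c", initial_count=counts[sid]) for sid in local
        ]
        submodels.append(
            Submodel(
                id=smid,
                formalism=Formalism.SSA if k % 2 == 0 else Formalism.ODE,
                compartments=[comp],
                species=species,
                reactions=reactions,
            )
        )
        for sid in local:
            mapping[(smid, sid)] = sid

    # only species actually declared by a submodel enter the global pool
    counts = {sid: counts[sid] for sid in sorted({g for g in mapping.values()})}
    model = merge_shared_species(submodels, mapping, initial_counts=counts)
    manifest = {
        "submodels": [
            {
                "id": sm.id,
                "file": f"{sm.id}.xml",
                "formalism": sm.formalism.value,
                "species_map": {sp.id: sp.id for sp in sm.species},
            }
            for sm in submodels
        ],
        "global_initial_counts": counts,
        "parameters": {},
    }
    return model, manifest
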