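"""Executable fixtures: worked contradiction examples and random planted
ontologies.

``worked_example`` returns small OBO documents encoding the classic
cross-ontology contradiction patterns — a locally contradictory
cross-product (spore), a global clash inferred across ontologies
(leukocyte activation), a homonymy clash (mucus secretion), a
double-cause clash through functional inheres_in plus quality constraints
(liver inflammation), an improper relation use (host cell cytoplasm part),
a cross-ontology retrieval query (vasculature) and an ambiguous-relation
repair scenario (has_central_participant).  Every bundle carries the
expected reasoner outcome, fixed by construction, never by running the
reasoner.

``generate_planted`` builds random OBO documents with a satisfiable
background taxonomy and a configurable number of planted contradictions
per category, together with the ground-truth unsatisfiable set (the
planted classes plus their existential-dependency closure, computed by a
graph walk over the document — independent of the tableau).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .convert import (
    MATERIAL_OBJECT,
    PROCESS,
    QUALITY,
    FUNCTION,
    ConversionConfig,
    TemplateRegistry,
    builtin_disambiguation_rules,
    builtin_templates,
)
from .obo import OboDocument, TermFrame, TypedefFrame


@dataclass
class FixtureBundle:
    name: str
    document: OboDocument
    config: ConversionConfig
    #: expected outcomes, keyed by kind ("unsatisfiable", "subsumptions",
    #: "queries", "resolution", ...)
    expected: Dict[str, object] = field(default_factory=dict)
    #: named variants (modified document or config)
    variants: Dict[str, "FixtureBundle"] = field(default_factory=dict)
    notes: str = ""


def _term(
    id: str,
    name: Optional[str] = None,
    namespace: Optional[str] = None,
    is_a: Sequence[str] = (),
    relationship: Sequence[Tuple[str, str]] = (),
    intersection_of: Sequence[Tuple[Optional[str], str]] = (),
    disjoint_from: Sequence[str] = (),
) -> TermFrame:
    return TermFrame(
        id=id,
        name=name or id.split(":", 1)[-1],
        namespace=namespace,
        is_a=list(is_a),
        relationship=list(relationship),
        intersection_of=list(intersection_of),
        disjoint_from=list(disjoint_from),
    )


def _doc(terms: Sequence[TermFrame], typedefs: Sequence[TypedefFrame] = (),
         source: str = "<fixture>") -> OboDocument:
    return OboDocument(
        header=[("format-version", "1.2")],
        terms=list(terms),
        typedefs=list(typedefs),
        source=source,
    )


WORKED_EXAMPLES = (
    "spore",
    "leukocyte_activation",
    "mucus_secretion",
    "liver_inflammation",
    "host_cell_cytoplasm_part",
    "vasculature_query",
    "hcp_disambiguation",
)


def worked_example(name: str) -> FixtureBundle:
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown worked example {name!r}; choose from {WORKED_EXAMPLES}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


def _spore() -> FixtureBundle:
    """A local contradiction: a spore defined as the intersection of fungal
    cell and prokaryotic cell, while fungal cells are eukaryotic cells,
    disjoint from prokaryotic cells.  The contradiction propagates through
    the classes defined in terms of the spore."""
    terms = [
        _term("CL:EukaryoticCell", disjoint_from=["CL:ProkaryoticCell"]),
        _term("CL:ProkaryoticCell"),
        _term("CL:FungalCell", is_a=["CL:EukaryoticCell"]),
        _term("CL:Spore", intersection_of=[(None, "CL:FungalCell"),
                                           (None, "CL:ProkaryoticCell")]),
        _term("GO:Sporulation", namespace="biological_process"),
        _term(
            "GO:SporulationResultingInFormationOfACellularSpore",
            namespace="biological_process",
            intersection_of=[(None, "GO:Sporulation"), ("has_output", "CL:Spore")],
        ),
        _term(
            "GO:SporeWallBiogenesis", namespace="biological_process",
            relationship=[("part_of", "GO:SporulationResultingInFormationOfACellularSpore")],
        ),
        _term(
            "GO:SporeWallAssembly", namespace="biological_process",
            relationship=[("part_of", "GO:SporeWallBiogenesis")],
        ),
    ]
    cfg = ConversionConfig(root_map={"CL": MATERIAL_OBJECT})
    expected = {
        "unsatisfiable": {
            "CL:Spore",
            "GO:SporulationResultingInFormationOfACellularSpore",
            "GO:SporeWallBiogenesis",
            "GO:SporeWallAssembly",
        }
    }
    return FixtureBundle("spore", _doc(terms, source="spore.obo"), cfg, expected)


def _leukocyte() -> FixtureBundle:
    """A global contradiction across an anatomy and a process ontology:
    leukocyte activation is a cellular process, yet inferred to be a system
    process (hence a multicellular organismal process, disjoint from
    cellular processes) because the immune system is an anatomical system."""
    typedefs = [
        TypedefFrame(id="has_agent", name="has agent",
                     domain=PROCESS, range=MATERIAL_OBJECT),
    ]
    terms = [
        _term("GO:BiologicalProcess", namespace="biological_process"),
        _term("GO:CellularProcess", namespace="biological_process",
              is_a=["GO:BiologicalProcess"]),
        _term("GO:MulticellularOrganismalProcess", namespace="biological_process",
              is_a=["GO:BiologicalProcess"], disjoint_from=["GO:CellularProcess"]),
        _term("GO:CellActivation", namespace="biological_process",
              is_a=["GO:CellularProcess"]),
        _term(
            "GO:SystemProcess", namespace="biological_process",
            is_a=["GO:MulticellularOrganismalProcess"],
            intersection_of=[(None, "GO:BiologicalProcess"),
                             ("has_agent", "UBERON:AnatomicalSystem")],
        ),
        _term(
            "GO:ImmuneSystemProcess", namespace="biological_process",
            intersection_of=[(None, "GO:BiologicalProcess"),
                             ("has_agent", "UBERON:ImmuneSystem")],
        ),
        _term(
            "GO:LeukocyteActivation", namespace="biological_process",
            is_a=["GO:ImmuneSystemProcess"],
            intersection_of=[(None, "GO:CellActivation"),
                             ("has_input", "CL:Leukocyte")],
        ),
        _term("UBERON:AnatomicalSystem"),
        _term("UBERON:ImmuneSystem", is_a=["UBERON:AnatomicalSystem"]),
        _term("CL:Leukocyte"),
    ]
    cfg = ConversionConfig(
        root_map={"UBERON": MATERIAL_OBJECT, "CL": MATERIAL_OBJECT}
    )
    expected = {
        "unsatisfiable": {"GO:LeukocyteActivation"},
        "subsumptions": [("GO:SystemProcess", "GO:ImmuneSystemProcess", True)],
    }
    return FixtureBundle(
        "leukocyte_activation", _doc(terms, typedefs, source="leukocyte.obo"),
        cfg, expected,
    )


def _mucus() -> FixtureBundle:
    """A homonymy contradiction: the cross-product uses the anatomical
    (material) Secretion where the process sense was meant; the
    results_in_* composite relation demands a process subject."""
    terms = [
        _term("UBERON:Secretion"),
        _term("GO:Secretion", namespace="biological_process"),
        _term("CHEBI:Mucus"),
        _term(
            "GO:MucusSecretion",
            intersection_of=[(None, "UBERON:Secretion"),
                             ("results_in_release_of", "CHEBI:Mucus")],
        ),
    ]
    cfg = ConversionConfig(
        root_map={"UBERON": MATERIAL_OBJECT, "CHEBI": MATERIAL_OBJECT}
    )
    bundle = FixtureBundle(
        "mucus_secretion", _doc(terms, source="mucus.obo"), cfg,
        {"unsatisfiable": {"GO:MucusSecretion"}},
    )
    # corrected variant: the process-sense Secretion prevents the error
    fixed = [
        _term("UBERON:Secretion"),
        _term("GO:Secretion", namespace="biological_process"),
        _term("CHEBI:Mucus"),
        _term(
            "GO:MucusSecretion",
            intersection_of=[(None, "GO:Secretion"),
                             ("results_in_release_of", "CHEBI:Mucus")],
        ),
    ]
    bundle.variants["go_secretion"] = FixtureBundle(
        "mucus_secretion/go_secretion", _doc(fixed, source="mucus_fixed.obo"),
        cfg, {"unsatisfiable": set()},
    )
    return bundle


def _liver() -> FixtureBundle:
    """A double-cause global contradiction: liver inflammation is a quality
    inhering in an inflammatory response (a process) while its asserted
    parent makes it inhere in the liver (a material object).  Functional
    inheres_in merges the two bearers into one impossible thing; the
    process-quality/physical-quality constraints independently force the
    same clash.  Only removing both causes makes the class satisfiable."""
    terms = [
        _term("PATO:ProcessualQuality"),
        _term("PATO:PhysicalQuality"),
        _term("PATO:Functionality", is_a=["PATO:PhysicalQuality"]),
        _term("PATO:IncreasedRate", is_a=["PATO:ProcessualQuality"]),
        _term("MA:Liver"),
        _term("GO:InflammatoryResponse", namespace="biological_process"),
        _term(
            "GO:LiverInflammatoryResponse", namespace="biological_process",
            intersection_of=[(None, "GO:InflammatoryResponse"),
                             ("has_participant", "MA:Liver")],
        ),
        _term(
            "MP:AbnormalLiverPhysiology",
            intersection_of=[(None, "PATO:Functionality"),
                             ("inheres_in", "MA:Liver")],
        ),
        _term(
            "MP:LiverInflammation",
            is_a=["MP:AbnormalLiverPhysiology"],
            intersection_of=[(None, "PATO:IncreasedRate"),
                             ("inheres_in", "GO:LiverInflammatoryResponse")],
        ),
    ]
    cfg = ConversionConfig(
        root_map={"PATO": QUALITY, "MA": MATERIAL_OBJECT, "MP": QUALITY},
        add_quality_constraints=True,
        process_quality_root="PATO:ProcessualQuality",
        physical_quality_root="PATO:PhysicalQuality",
    )
    doc = _doc(terms, source="liver.obo")
    bundle = FixtureBundle(
        "liver_inflammation", doc, cfg,
        {"unsatisfiable": {"MP:LiverInflammation"}},
    )
    no_constraints = ConversionConfig(
        root_map=dict(cfg.root_map), add_quality_constraints=False
    )
    bundle.variants["no_quality_constraints"] = FixtureBundle(
        "liver_inflammation/no_quality_constraints", doc, no_constraints,
        {"unsatisfiable": {"MP:LiverInflammation"}},
        notes="functional inheres_in alone still closes the clash",
    )
    return bundle


def _host_cell() -> FixtureBundle:
    """Improper use of a well-defined relation: inheres_in between two
    material objects makes the subject a Quality, disjoint from its
    asserted material parent — unsatisfiability follows purely from the
    inheres_in domain axiom."""
    terms = [
        _term("GO:HostCellPart", namespace="cellular_component"),
        _term("GO:Cytoplasm", namespace="cellular_component"),
        _term(
            "GO:HostCellCytoplasmPart",
            intersection_of=[(None, "GO:HostCellPart"),
                             ("inheres_in", "GO:Cytoplasm")],
        ),
    ]
    cfg = ConversionConfig()
    return FixtureBundle(
        "host_cell_cytoplasm_part", _doc(terms, source="hostcell.obo"), cfg,
        {"unsatisfiable": {"GO:HostCellCytoplasmPart"}},
    )


VASCULATURE_QUERY = (
    "Quality and inheres_in some (part_of some "
    "(MA:AbdomenOrgan and has_part some MA:BloodVessel))"
)


def _vasculature() -> FixtureBundle:
    """Cross-ontology retrieval: phenotypes of the vasculature of abdominal
    organs are found only because inheres_in_part_of expands into the
    primitive inheres_in/part_of relations, enabling inference over the
    anatomy ontology's parthood.  The kidney phenotype is retrieved only
    once the missing 'kidney blood vessel is a blood vessel' assertion is
    added."""
    def terms(kidney_link: bool):
        kbv = _term("MA:KidneyBloodVessel",
                    is_a=["MA:BloodVessel"] if kidney_link else [])
        return [
            _term("MA:AbdomenOrgan"),
            _term("MA:VascularSystem"),
            _term("MA:BloodVessel",
                  relationship=[("part_of", "MA:VascularSystem")]),
            kbv,
            _term("MA:Liver", is_a=["MA:AbdomenOrgan"],
                  relationship=[("has_part", "MA:BloodVessel")]),
            _term("MA:Kidney", is_a=["MA:AbdomenOrgan"],
                  relationship=[("has_part", "MA:KidneyBloodVessel")]),
            _term("MA:Brain"),
            _term("PATO:Congested"),
            _term("PATO:Abnormal"),
            _term(
                "MP:LiverVascularCongestion",
                intersection_of=[(None, "PATO:Congested"),
                                 ("inheres_in_part_of", "MA:Liver")],
            ),
            _term(
                "MP:AbnormalLiverVasculature",
                intersection_of=[(None, "PATO:Abnormal"),
                                 ("inheres_in_part_of", "MA:Liver")],
            ),
            _term(
                "MP:AbnormalRenalPlasmaFlowRate",
                intersection_of=[(None, "PATO:Abnormal"),
                                 ("inheres_in_part_of", "MA:Kidney")],
            ),
            _term(
                "MP:AbnormalBrainMorphology",
                intersection_of=[(None, "PATO:Abnormal"),
                                 ("inheres_in_part_of", "MA:Brain")],
            ),
        ]

    cfg = ConversionConfig(
        root_map={"MA": MATERIAL_OBJECT, "PATO": QUALITY, "MP": QUALITY}
    )
    liver_answers = {"MP:LiverVascularCongestion", "MP:AbnormalLiverVasculature"}
    bundle = FixtureBundle(
        "vasculature_query", _doc(terms(False), source="vasculature.obo"), cfg,
        {"unsatisfiable": set(),
         "queries": {VASCULATURE_QUERY: liver_answers}},
    )
    bundle.variants["kidney_link"] = FixtureBundle(
        "vasculature_query/kidney_link",
        _doc(terms(True), source="vasculature_kidney.obo"), cfg,
        {"queries": {VASCULATURE_QUERY:
                     liver_answers | {"MP:AbnormalRenalPlasmaFlowRate"}}},
    )
    # without the inheres_in_part_of expansion the relation stays opaque and
    # the query cannot see the anatomy ontology's parthood structure
    no_exp_registry = TemplateRegistry()
    del no_exp_registry.templates["inheres_in_part_of"]
    no_exp = ConversionConfig(registry=no_exp_registry, root_map=dict(cfg.root_map))
    bundle.variants["no_expansion"] = FixtureBundle(
        "vasculature_query/no_expansion",
        _doc(terms(False), source="vasculature.obo"), no_exp,
        {"queries": {VASCULATURE_QUERY: set()}},
    )
    return bundle


def _hcp() -> FixtureBundle:
    """Repair scenario: quality classes misuse has_central_participant (a
    process-to-material relation); one process class uses it properly, and
    one class carries an unrelated disjointness clash that repair must not
    remove."""
    terms = [
        _term("PATO:Degenerate"),
        _term("PATO:Decreased"),
        _term("MA:Muscle"),
        _term("MA:Neuron"),
        _term("MA:SomeTissue"),
        _term("GO:SomeProcess", namespace="biological_process"),
        _term(
            "MP:MuscleDegeneration",
            intersection_of=[(None, "PATO:Degenerate"),
                             ("has_central_participant", "MA:Muscle")],
        ),
        _term(
            "MP:NeuronLoss",
            intersection_of=[(None, "PATO:Decreased"),
                             ("has_central_participant", "MA:Neuron")],
        ),
        _term(
            "GO:MuscleContraction", namespace="biological_process",
            relationship=[("has_central_participant", "MA:Muscle")],
        ),
        _term(
            "MP:BrokenClass",
            intersection_of=[(None, "GO:SomeProcess"), (None, "MA:SomeTissue")],
        ),
    ]
    root_map = {"PATO": QUALITY, "MA": MATERIAL_OBJECT, "MP": QUALITY}
    strict = ConversionConfig(root_map=dict(root_map))
    rules = builtin_disambiguation_rules()
    disamb = ConversionConfig(
        root_map=dict(root_map),
        disambiguation={"has_central_participant":
                        rules["has_central_participant"]},
    )
    doc = _doc(terms, source="hcp.obo")
    bundle = FixtureBundle(
        "hcp_disambiguation", doc, disamb,
        {
            "unsatisfiable": {"MP:BrokenClass"},
            "strict_unsatisfiable": {
                "MP:MuscleDegeneration", "MP:NeuronLoss", "MP:BrokenClass",
            },
            "resolution": {
                ("MP:MuscleDegeneration", "has_central_participant", "MA:Muscle"):
                    "unintended",
                ("MP:NeuronLoss", "has_central_participant", "MA:Neuron"):
                    "unintended",
                ("GO:MuscleContraction", "has_central_participant", "MA:Muscle"):
                    "intended",
            },
        },
    )
    bundle.variants["strict"] = FixtureBundle(
        "hcp_disambiguation/strict", doc, strict,
        {"unsatisfiable": {
            "MP:MuscleDegeneration", "MP:NeuronLoss", "MP:BrokenClass"}},
    )
    return bundle


_BUILDERS = {
    "spore": _spore,
    "leukocyte_activation": _leukocyte,
    "mucus_secretion": _mucus,
    "liver_inflammation": _liver,
    "host_cell_cytoplasm_part": _host_cell,
    "vasculature_query": _vasculature,
    "hcp_disambiguation": _hcp,
}


# ---------------------------------------------------------------------------
# Random planted-contradiction generator
# ---------------------------------------------------------------------------

PLANT_CATEGORIES = (
    "disjoint_intersection",
    "domain_violation",
    "homonymy_merge",
    "functional_merge_clash",
    "ambiguous_relation_use",
)

_FAMILY_PREFIXES = {
    MATERIAL_OBJECT: "XM",
    PROCESS: "XP",
    QUALITY: "XQ",
    FUNCTION: "XF",
}


@dataclass
class PlantSpec:
    seed: int
    n_classes: int = 24
    depth: int = 4
    n_dependents: int = 2
    plants: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for cat in self.plants:
            if cat not in PLANT_CATEGORIES:
                raise ValueError(f"unknown plant category {cat!r}")
        if self.n_classes < 8:
            raise ValueError("need at least 8 background classes (2 per family)")
        if sum(self.plants.values()) > self.n_classes:
            raise ValueError("more plants than background classes")


def generate_planted(spec: PlantSpec) -> FixtureBundle:
    """Random OBO document with planted contradictions and ground truth.

    The background is a per-family is-a forest (families pre-assigned to the
    four upper-level roots via identifier prefixes) decorated with
    type-safe relationships; each plant adds fresh classes exhibiting one
    contradiction pattern, plus optional dependent classes whose
    definitions reference the planted class through an existential
    restriction (so unsatisfiability propagates to them).

    ``expected["unsatisfiable"]`` is the planted set closed under
    existential dependency, computed by a reachability walk over the
    document itself; ``expected["disambiguated_unsatisfiable"]`` excludes
    the ambiguity-caused plants (which disjunctive expansion repairs).
    Identical specs yield byte-identical documents.
    """
    rng = random.Random(spec.seed)
    families = {f: [] for f in _FAMILY_PREFIXES}
    counter = [0]

    def new_class(family: str) -> str:
        counter[0] += 1
        return f"{_FAMILY_PREFIXES[family]}:{counter[0]:04d}"

    terms: List[TermFrame] = []

    def add_term(family: str, **kw) -> str:
        cid = new_class(family)
        terms.append(_term(cid, **kw))
        families[family].append(cid)
        return cid

    # background taxonomy: 2+ classes per family, random parent among the
    # earlier classes of the same family (bounded depth)
    fam_list = list(_FAMILY_PREFIXES)
    for f in fam_list:
        add_term(f)
        add_term(f, is_a=[families[f][0]])
    depths: Dict[str, int] = {}
    for f in fam_list:
        depths[families[f][0]] = 0
        depths[families[f][1]] = 1
    for _ in range(spec.n_classes - 8):
        f = rng.choice(fam_list)
        candidates = [c for c in families[f] if depths[c] < spec.depth]
        parent = rng.choice(candidates or families[f])
        cid = add_term(f, is_a=[parent])
        depths[cid] = depths.get(parent, 0) + 1

    # type-safe decorations (never contradictory on their own)
    def decorate():
        mats, procs, quals = (
            families[MATERIAL_OBJECT], families[PROCESS], families[QUALITY]
        )
        for t in terms:
            fam = _prefix_family(t.id)
            r = rng.random()
            if fam == MATERIAL_OBJECT and r < 0.4:
                t.relationship.append(("part_of", rng.choice(mats)))
            elif fam == PROCESS and r < 0.4:
                rel = rng.choice(["has_participant", "has_input", "has_output"])
                t.relationship.append((rel, rng.choice(mats)))
            elif fam == QUALITY and r < 0.4 and not any(
                rel == "inheres_in" for rel, _ in t.relationship
            ):
                t.relationship.append(("inheres_in", rng.choice(mats)))
            elif fam == FUNCTION and r < 0.3:
                t.relationship.append(("function_of", rng.choice(mats)))

    decorate()

    # plants and dependents draw their hosts/fillers from the satisfiable
    # background only, so the ground truth stays exact by construction
    background = {f: list(cs) for f, cs in families.items()}

    planted: List[Tuple[str, str]] = []  # (class id, category)

    def plant(category: str) -> str:
        mats, procs, quals = (
            background[MATERIAL_OBJECT], background[PROCESS], background[QUALITY]
        )
        if category == "disjoint_intersection":
            host = rng.choice(mats)
            a = add_term(MATERIAL_OBJECT, is_a=[host])
            b = add_term(MATERIAL_OBJECT, is_a=[host])
            terms[-1].disjoint_from.append(a)  # b disjoint_from a
            cid = add_term(
                MATERIAL_OBJECT,
                intersection_of=[(None, a), (None, b)],
            )
        elif category == "domain_violation":
            cid = add_term(
                QUALITY,
                is_a=[rng.choice(quals)],
                relationship=[(rng.choice(["has_input", "has_output"]),
                               rng.choice(mats))],
            )
        elif category == "homonymy_merge":
            cid = add_term(
                MATERIAL_OBJECT,
                intersection_of=[(None, rng.choice(mats)),
                                 ("results_in_release_of", rng.choice(mats))],
            )
        elif category == "functional_merge_clash":
            cid = add_term(
                QUALITY,
                is_a=[rng.choice(quals)],
                relationship=[("inheres_in", rng.choice(mats)),
                              ("inheres_in", rng.choice(procs))],
            )
        elif category == "ambiguous_relation_use":
            # fresh genus: must carry no inheres_in of its own, or the
            # repaired reading would clash with it via functionality
            genus = add_term(QUALITY)
            cid = add_term(
                QUALITY,
                intersection_of=[(None, genus),
                                 ("has_central_participant", rng.choice(mats))],
            )
        else:  # pragma: no cover
            raise ValueError(category)
        planted.append((cid, category))
        return cid

    for category in PLANT_CATEGORIES:
        for _ in range(spec.plants.get(category, 0)):
            plant(category)

    # dependent classes: reference a planted class through an existential
    # restriction or an is-a edge, so the contradiction propagates
    dependents: List[Tuple[str, str]] = []  # (dependent, plant it depends on)
    for base, _cat in list(planted):
        chain_from = base
        for _ in range(rng.randint(0, spec.n_dependents)):
            fam = _prefix_family(chain_from)
            kind = rng.random()
            if kind < 0.4:
                cid = add_term(fam, is_a=[chain_from])
            elif kind < 0.7 or fam != MATERIAL_OBJECT:
                cid = add_term(fam, relationship=[("part_of", chain_from)])
            else:
                # has_participant has range MaterialObject, so this shape is
                # only type-safe toward material plants
                cid = add_term(
                    PROCESS,
                    intersection_of=[(None, background[PROCESS][0]),
                                     ("has_participant", chain_from)],
                )
            dependents.append((cid, base))
            chain_from = cid

    doc = _doc(terms, source=f"planted-{spec.seed}.obo")

    cfg = ConversionConfig(
        root_map={p: f for f, p in _FAMILY_PREFIXES.items()},
    )
    rules = builtin_disambiguation_rules()
    disamb_cfg = ConversionConfig(
        root_map=dict(cfg.root_map),
        disambiguation={"has_central_participant":
                        rules["has_central_participant"]},
    )

    plant_bases = {cid for cid, _ in planted}
    ambiguous_bases = {cid for cid, cat in planted
                       if cat == "ambiguous_relation_use"}
    strict_unsat = _dependency_closure(doc, plant_bases)
    disamb_unsat = _dependency_closure(doc, plant_bases - ambiguous_bases)

    expected = {
        "unsatisfiable": strict_unsat,
        "disambiguated_unsatisfiable": disamb_unsat,
        "planted": dict(planted),
        "resolution": {
            (cid, "has_central_participant", filler): "unintended"
            for cid, cat in planted if cat == "ambiguous_relation_use"
            for rel, filler in _xp_relations(doc, cid)
            if rel == "has_central_participant"
        },
    }
    bundle = FixtureBundle(
        f"planted-{spec.seed}", doc, cfg, expected,
    )
    bundle.variants["disambiguated"] = FixtureBundle(
        f"planted-{spec.seed}/disambiguated", doc, disamb_cfg,
        {"unsatisfiable": disamb_unsat},
    )
    return bundle


def _prefix_family(cid: str) -> str:
    pfx = cid.split(":", 1)[0]
    for fam, p in _FAMILY_PREFIXES.items():
        if p == pfx:
            return fam
    raise ValueError(cid)


def _xp_relations(doc: OboDocument, cid: str):
    t = doc.term(cid)
    out = [(rel, tgt) for rel, tgt in t.relationship]
    out += [(rel, tgt) for rel, tgt in t.intersection_of if rel is not None]
    return out


# ---------------------------------------------------------------------------
# Random ALC + transitive-roles ontologies (reasoner cross-check corpus)
# ---------------------------------------------------------------------------


def random_alc_ontology(
    seed: int,
    n_classes: int = 4,
    n_roles: int = 2,
    n_axioms: int = 6,
):
    """A random small ontology in the ALC + role-hierarchy + transitive-roles
    fragment, for cross-checking the tableau against exhaustive bounded
    model search.

    The fragment deliberately excludes inverse and functional roles (those
    lack small forced models and are exercised by the worked examples
    instead); expressions stay shallow so any satisfiable ontology here has
    a model within a handful of elements.
    """
    from .dl import (
        And as _And, DisjointClasses as _Dis, Named as _Named, Not as _Not,
        Only as _Only, Ontology as _Ontology, Or as _Or,
        RoleDeclaration as _Role, Some as _Some, SubClassOf as _Sub,
    )

    rng = random.Random(seed)
    classes = [f"A{i}" for i in range(rng.randint(2, n_classes))]
    roles = [f"r{i}" for i in range(rng.randint(1, n_roles))]
    o = _Ontology()
    for c in classes:
        o.declare_class(c)
    for i, r in enumerate(roles):
        decl = _Role(id=r, transitive=rng.random() < 0.4)
        if i > 0 and rng.random() < 0.3:
            decl.super_roles.add(roles[0])
        o.declare_role(decl)

    def literal():
        c = _Named(rng.choice(classes))
        return _Not(c) if rng.random() < 0.3 else c

    def shallow():
        k = rng.random()
        if k < 0.35:
            return literal()
        if k < 0.5:
            op = _And if rng.random() < 0.5 else _Or
            return op.of(literal(), literal())
        if k < 0.75:
            return _Some(rng.choice(roles), literal())
        return _Only(rng.choice(roles), literal())

    for _ in range(rng.randint(1, n_axioms)):
        k = rng.random()
        if k < 0.15 and len(classes) >= 2:
            a, b = rng.sample(classes, 2)
            o.add_axiom(_Dis([_Named(a), _Named(b)]), "random")
        else:
            o.add_axiom(_Sub(_Named(rng.choice(classes)), shallow()), "random")
    # a compound expression to test alongside the named classes
    probe = _And.of(literal(), shallow())
    return o, probe


# relations whose template expansion is an existential restriction, hence
# propagate unsatisfiability from filler to subject
_TEMPLATE_NAMES = frozenset(builtin_templates())
_EXISTENTIAL_RELATIONS = {
    name for name, t in builtin_templates().items()
    if repr(t.body).startswith("Some(")
}


def _dependency_closure(doc: OboDocument, seeds: Set[str]) -> Set[str]:
    """Classes unsatisfiable because they are seeds or reference one through
    is_a, an existential relationship, or a definition conjunct.

    Graph walk over the document only; independent of the reasoner.
    """
    # reverse edges: target -> dependents
    rev: Dict[str, Set[str]] = {}

    def dep(src: str, tgt: str):
        rev.setdefault(tgt, set()).add(src)

    for t in doc.terms:
        for p in t.is_a:
            dep(t.id, p)
        for rel, tgt in t.relationship:
            if rel in _EXISTENTIAL_RELATIONS or rel not in _TEMPLATE_NAMES:
                dep(t.id, tgt)
        for rel, tgt in t.intersection_of:
            dep(t.id, tgt)  # any dead conjunct kills the intersection
    out = set(seeds)
    frontier = list(seeds)
    while frontier:
        x = frontier.pop()
        for y in rev.get(x, ()):
            if y not in out:
                out.add(y)
                frontier.append(y)
    return out
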