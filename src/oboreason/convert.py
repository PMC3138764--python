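"""Conversion of OBO documents into description-logic axiom sets.

This is the heart of the method: class-class relations in OBO files are
treated as *single-argument templates* that unfold into class expressions.
``Nucleus relationship: part_of Cell`` becomes
``Nucleus SubClassOf: part_of some Cell``; a cross-product
(``intersection_of``) definition becomes an equivalence between the defined
class and the intersection of its genus and expanded differentia.  The
resulting axioms are merged with a minimal upper-level ontology (four
mutually disjoint classes: MaterialObject, Process, Quality, Function,
plus axiomatized relations) and with per-prefix root assignments, so that
an automated reasoner can detect contradictory definitions across
ontologies.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .dl import (
    And,
    Bottom,
    ClassExpression,
    DisjointClasses,
    EquivalentClasses,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    RoleDeclaration,
    Some,
    SubClassOf,
    Top,
    replace_subexpression,
)
from .manchester import parse_expression, to_manchester
from .obo import OboDocument, TermFrame, TypedefFrame

# Upper-level class identifiers
MATERIAL_OBJECT = "MaterialObject"
PROCESS = "Process"
QUALITY = "Quality"
FUNCTION = "Function"
UPPER_CLASSES = (MATERIAL_OBJECT, PROCESS, QUALITY, FUNCTION)

#: placeholder used in template bodies
PLACEHOLDER = Named("?Y")


class ConfigError(ValueError):
    """Invalid conversion configuration (prefix collisions, bad roots...)."""


# ---------------------------------------------------------------------------
# Upper-level ontology
# ---------------------------------------------------------------------------


def build_upper_ontology() -> Ontology:
    """The minimal four-class upper-level ontology with axiomatized relations.

    MaterialObject, Process, Quality and Function are pairwise disjoint.
    Relations carry the domain/range/inverse axioms of the method:
    inheres_in is functional (a quality inheres in at most one thing) with
    range Thing; part_of is transitive and reflexive with inverse has_part;
    proper_part_of is a transitive sub-relation of part_of; has_input,
    has_output and has_central_participant are sub-relations of
    has_participant.
    """
    o = Ontology()
    for c in UPPER_CLASSES:
        o.declare_class(c)
    o.add_axiom(
        DisjointClasses([Named(c) for c in UPPER_CLASSES]), "upper-ontology"
    )

    MO, PR, QU, FN = (Named(c) for c in UPPER_CLASSES)

    def role(rid, **kw):
        decl = RoleDeclaration(id=rid, **kw)
        o.declare_role(decl)
        return decl

    role("function_of", domain=FN, range=MO, inverse="has_function")
    role("has_function", domain=MO, range=FN, inverse="function_of")
    role("inheres_in", domain=QU, range=None, functional=True, inverse="has_quality")
    role("has_quality", domain=None, range=QU, inverse="inheres_in")
    role("derives_from", domain=MO, range=MO)
    role("has_participant", domain=PR, range=MO, inverse="participates_in")
    role("participates_in", domain=MO, range=PR, inverse="has_participant")
    role("has_input", domain=PR, range=MO, inverse="input_of",
         super_roles={"has_participant"})
    role("input_of", domain=MO, range=PR, inverse="has_input",
         super_roles={"participates_in"})
    role("has_output", domain=PR, range=MO, inverse="output_of",
         super_roles={"has_participant"})
    role("output_of", domain=MO, range=PR, inverse="has_output",
         super_roles={"participates_in"})
    role("has_central_participant", domain=PR, range=MO,
         inverse="central_participant_of", super_roles={"has_participant"})
    role("central_participant_of", domain=MO, range=PR,
         inverse="has_central_participant", super_roles={"participates_in"})
    role("part_of", transitive=True, reflexive=True, inverse="has_part")
    role("has_part", transitive=True, reflexive=True, inverse="part_of")
    role("proper_part_of", transitive=True, inverse="has_proper_part",
         super_roles={"part_of"})
    role("has_proper_part", transitive=True, inverse="proper_part_of",
         super_roles={"has_part"})
    role("realized_by", domain=FN, range=PR, inverse="realizes")
    role("realizes", domain=PR, range=FN, inverse="realized_by")
    role("results_in", domain=PR, range=PR)
    return o


# ---------------------------------------------------------------------------
# Relation templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationTemplate:
    """A class-expression body with exactly one ``?Y`` placeholder."""

    name: str
    body: ClassExpression

    def __post_init__(self):
        n = _count_placeholder(self.body)
        if n != 1:
            raise ValueError(
                f"template {self.name!r} must contain exactly one ?Y (found {n})"
            )


def _count_placeholder(e: ClassExpression) -> int:
    if e == PLACEHOLDER:
        return 1
    if isinstance(e, Not):
        return _count_placeholder(e.arg)
    if isinstance(e, (And, Or)):
        return sum(_count_placeholder(a) for a in e.args)
    if isinstance(e, (Some, Only)):
        return _count_placeholder(e.filler)
    return 0


def expand_template(t: RelationTemplate, filler: ClassExpression) -> ClassExpression:
    """Substitute *filler* for the template's ``?Y`` placeholder."""
    return replace_subexpression(t.body, PLACEHOLDER, filler)


def template(name: str, body: str) -> RelationTemplate:
    return RelationTemplate(name, parse_expression(body))


def builtin_templates() -> Dict[str, RelationTemplate]:
    """The built-in template registry.

    Composite relations unfold into nested restrictions over the primitive
    upper-level relations; plain relations unfold into a single existential
    restriction.
    """
    specs = {
        # composite relations
        "inheres_in_part_of": "inheres_in some (part_of some ?Y)",
        "has_function_realized_by": "has_function some (realized_by only ?Y)",
        "capable_of": "has_function some (realized_by only ?Y)",
        "inheres_in_has_central_participant":
            "inheres_in some (has_central_participant some ?Y)",
        "inheres_in_has_participant":
            "inheres_in some (has_participant some ?Y)",
        "realized_by_has_input": "realized_by only (has_input some ?Y)",
        "realized_by_has_output": "realized_by only (has_output some ?Y)",
        # primitive upper-level relations: plain existential restriction
        "part_of": "part_of some ?Y",
        "has_part": "has_part some ?Y",
        "proper_part_of": "proper_part_of some ?Y",
        "inheres_in": "inheres_in some ?Y",
        "has_quality": "has_quality some ?Y",
        "function_of": "function_of some ?Y",
        "has_function": "has_function some ?Y",
        "derives_from": "derives_from some ?Y",
        "has_participant": "has_participant some ?Y",
        "participates_in": "participates_in some ?Y",
        "has_input": "has_input some ?Y",
        "has_output": "has_output some ?Y",
        "has_central_participant": "has_central_participant some ?Y",
        "realized_by": "realized_by some ?Y",
        "realizes": "realizes some ?Y",
        "results_in": "results_in some ?Y",
    }
    return {name: template(name, body) for name, body in specs.items()}


@dataclass
class TemplateRegistry:
    """Total lookup of relation → template.

    Unregistered relations fall back to a plain existential restriction over
    a fresh role named after the relation; ``domain_rules`` then assign a
    domain class to fresh roles whose name matches a glob pattern (the
    ``results_in_*`` composites must have a process as first argument and
    are deliberately kept primitive).
    """

    templates: Dict[str, RelationTemplate] = field(default_factory=builtin_templates)
    domain_rules: List[Tuple[str, str]] = field(
        default_factory=lambda: [("results_in_*", PROCESS)]
    )

    def lookup(self, relation: str) -> RelationTemplate:
        t = self.templates.get(relation)
        if t is not None:
            return t
        return RelationTemplate(relation, Some(relation, PLACEHOLDER))

    def is_registered(self, relation: str) -> bool:
        return relation in self.templates

    def fresh_role_domain(self, relation: str) -> Optional[str]:
        for pattern, cls in self.domain_rules:
            if fnmatch.fnmatchcase(relation, pattern):
                return cls
        return None


# ---------------------------------------------------------------------------
# Synonym canonicalization
# ---------------------------------------------------------------------------

DEFAULT_SYNONYMS = {
    # hyphen/space variants are the same relation
    "has-part": "has_part", "has part": "has_part",
    "part-of": "part_of", "part of": "part_of",
    "inheres-in": "inheres_in", "inheres in": "inheres_in",
    "inheres-in-part-of": "inheres_in_part_of",
    "has-input": "has_input", "has-output": "has_output",
    "has-participant": "has_participant",
    "has-central-participant": "has_central_participant",
    "has-function": "has_function", "function-of": "function_of",
    "realized-by": "realized_by", "derives-from": "derives_from",
    "capable-of": "capable_of",
    "results-in": "results_in",
    "proper-part-of": "proper_part_of",
}


def canonical_relation(name: str, synonym_map: Mapping[str, str]) -> str:
    """Canonicalize a relation label/id through the synonym map.

    Hyphens and spaces normalize to underscores before lookup, so
    ``has_part``, ``has-part`` and ``has part`` all map to one role.
    """
    if name in synonym_map:
        return synonym_map[name]
    norm = re.sub(r"[-\s]+", "_", name.strip())
    return synonym_map.get(norm, norm)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DisambiguationRule:
    """Alternative readings for an ambiguously used relation.

    ``alternatives[0]`` is the intended meaning; ``replacement_names[i]``
    names the composite relation a use resolved to alternative *i* is
    rewritten to (``None`` = keep the original relation name).
    """

    relation: str
    alternatives: List[RelationTemplate]
    replacement_names: List[Optional[str]]

    def __post_init__(self):
        if len(self.alternatives) < 1:
            raise ValueError("need at least one alternative")
        if len(self.replacement_names) != len(self.alternatives):
            raise ValueError("one replacement name per alternative")


def builtin_disambiguation_rules() -> Dict[str, DisambiguationRule]:
    """The disambiguation rules for has_output, has_input, inheres_in and
    has_central_participant.

    Each rule's first alternative is the relation's intended meaning; the
    second reads the use as shorthand for a composite relation (a function
    realized by such a process, or a quality of such a process).  The
    Function conjunct on the realized_by readings anchors the otherwise
    vacuously satisfiable ``only`` restriction to function classes.
    """
    rules = [
        DisambiguationRule(
            "has_output",
            [template("has_output", "has_output some ?Y"),
             template("realized_by_has_output",
                      "Function and (realized_by only (has_output some ?Y))")],
            [None, "realized_by_has_output"],
        ),
        DisambiguationRule(
            "has_input",
            [template("has_input", "has_input some ?Y"),
             template("realized_by_has_input",
                      "Function and (realized_by only (has_input some ?Y))")],
            [None, "realized_by_has_input"],
        ),
        DisambiguationRule(
            "inheres_in",
            [template("inheres_in", "inheres_in some ?Y"),
             template("inheres_in_has_participant",
                      "inheres_in some (has_participant some ?Y)")],
            [None, "inheres_in_has_participant"],
        ),
        DisambiguationRule(
            "has_central_participant",
            [template("has_central_participant", "has_central_participant some ?Y"),
             template("inheres_in_has_central_participant",
                      "inheres_in some (has_central_participant some ?Y)")],
            [None, "inheres_in_has_central_participant"],
        ),
    ]
    return {r.relation: r for r in rules}


@dataclass
class ConversionConfig:
    registry: TemplateRegistry = field(default_factory=TemplateRegistry)
    #: identifier prefix (before the colon) → upper-level class
    root_map: Dict[str, str] = field(default_factory=dict)
    #: routing for GO terms by namespace; molecular_function follows mf_mode
    mf_mode: str = "function"  # "function" | "process"
    synonym_map: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    strip_asserted_isa: bool = False
    add_quality_constraints: bool = False
    #: PATO-style roots for the two quality constraint axioms
    process_quality_root: Optional[str] = None
    physical_quality_root: Optional[str] = None
    #: relations expanded disjunctively (repair mode); None = strict
    disambiguation: Dict[str, DisambiguationRule] = field(default_factory=dict)

    def __post_init__(self):
        if self.mf_mode not in ("function", "process"):
            raise ConfigError(f"mf_mode must be 'function' or 'process', got {self.mf_mode!r}")
        for prefix, cls in self.root_map.items():
            if cls not in UPPER_CLASSES:
                raise ConfigError(
                    f"root_map[{prefix!r}] = {cls!r} is not one of {UPPER_CLASSES}"
                )


GO_NAMESPACE_ROOTS = {
    "biological_process": PROCESS,
    "cellular_component": MATERIAL_OBJECT,
    # molecular_function routed per mf_mode
}


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------


def _prefix(identifier: str) -> str:
    return identifier.split(":", 1)[0] if ":" in identifier else identifier


def upper_root_for(term: TermFrame, cfg: ConversionConfig) -> Optional[str]:
    """Upper-level class a term is routed to, or None if no rule fires."""
    pfx = _prefix(term.id)
    if pfx == "GO" and term.namespace:
        ns = term.namespace
        if ns == "molecular_function":
            return FUNCTION if cfg.mf_mode == "function" else PROCESS
        if ns in GO_NAMESPACE_ROOTS:
            return GO_NAMESPACE_ROOTS[ns]
    return cfg.root_map.get(pfx)


def convert(docs: Sequence[OboDocument], cfg: ConversionConfig) -> Ontology:
    """Convert OBO documents into a single Ontology.

    Per non-obsolete term C:

    * ``is_a: D``            → ``SubClassOf(C, D)`` (dropped when
      ``strip_asserted_isa``)
    * ``relationship: R D``  → ``SubClassOf(C, expand(template(R), D))``
    * ``intersection_of``    → ``EquivalentClasses(C, And(conjuncts))``
    * ``disjoint_from: D``   → ``DisjointClasses(C, D)``

    Relation names are canonicalized through the synonym map first.
    Relations with a disambiguation rule in the config expand to the
    disjunction of their alternatives, and each use site is recorded on the
    ontology for later resolution.  Unregistered relations fall back to a
    fresh role; ``results_in_*`` fresh roles receive domain Process.
    The upper-level ontology, root assignments and (optionally) the quality
    constraints are merged in.  Axioms carry file:line provenance.
    """
    o = build_upper_ontology()
    declared: set = set()
    for doc in docs:
        declared |= doc.term_ids() | doc.typedef_ids()

    # role metadata from typedef stanzas (registry templates win on conflict;
    # non-conflicting metadata is merged)
    for doc in docs:
        for td in doc.typedefs:
            rid = canonical_relation(td.id, cfg.synonym_map)
            decl = o.roles.setdefault(rid, RoleDeclaration(id=rid))
            decl.transitive = decl.transitive or td.is_transitive
            decl.symmetric = decl.symmetric or td.is_symmetric
            decl.reflexive = decl.reflexive or td.is_reflexive
            decl.functional = decl.functional or td.is_functional
            if td.domain and decl.domain is None:
                decl.domain = Named(td.domain)
            if td.range and decl.range is None:
                decl.range = Named(td.range)
            if td.inverse_of and decl.inverse is None:
                inv = canonical_relation(td.inverse_of, cfg.synonym_map)
                decl.inverse = inv
                o.roles.setdefault(inv, RoleDeclaration(id=inv)).inverse = rid
            for sup in td.is_a:
                decl.super_roles.add(canonical_relation(sup, cfg.synonym_map))

    def note_dangling(ref: str, where: str):
        if ref not in declared:
            o.dangling.append(f"{ref} (referenced at {where})")

    def expansion(cls_id: str, relation: str, target_id: str, where: str):
        """Expand one relation use; returns the class expression."""
        rel = canonical_relation(relation, cfg.synonym_map)
        filler = Named(target_id)
        note_dangling(target_id, where)
        rule = cfg.disambiguation.get(rel)
        if rule is not None:
            expr = disambiguated_expand(rule, filler)
            o.ambiguous_uses.append((cls_id, rel, target_id, expr))
            _ensure_roles(o, expr, cfg.registry)
            return expr
        if not cfg.registry.is_registered(rel):
            dom = cfg.registry.fresh_role_domain(rel)
            decl = o.roles.setdefault(rel, RoleDeclaration(id=rel))
            if dom is not None and decl.domain is None:
                decl.domain = Named(dom)
        return expand_template(cfg.registry.lookup(rel), filler)

    for doc in docs:
        for t in doc.terms:
            if t.is_obsolete:
                continue
            o.declare_class(t.id)
            where = f"{doc.source}:{t.line_no}"
            if not cfg.strip_asserted_isa:
                for parent in t.is_a:
                    note_dangling(parent, where)
                    o.add_axiom(SubClassOf(Named(t.id), Named(parent)),
                                f"{where}:is_a")
            for rel, tgt in t.relationship:
                o.add_axiom(
                    SubClassOf(Named(t.id), expansion(t.id, rel, tgt, where)),
                    f"{where}:relationship",
                )
            if t.intersection_of:
                conjuncts = []
                for rel, tgt in t.intersection_of:
                    if rel is None:
                        note_dangling(tgt, where)
                        conjuncts.append(Named(tgt))
                    else:
                        conjuncts.append(expansion(t.id, rel, tgt, where))
                o.add_axiom(
                    EquivalentClasses(Named(t.id), And.of(*conjuncts)),
                    f"{where}:intersection_of",
                )
            for d in t.disjoint_from:
                note_dangling(d, where)
                o.add_axiom(DisjointClasses([Named(t.id), Named(d)]),
                            f"{where}:disjoint_from")
            if t.union_of:
                o.dangling.append(
                    f"union_of on {t.id} at {where}: unsupported, ignored"
                )
            root = upper_root_for(t, cfg)
            if root is not None:
                o.add_axiom(SubClassOf(Named(t.id), Named(root)), "root-map")

    if cfg.add_quality_constraints:
        add_quality_constraints(
            o, cfg.process_quality_root, cfg.physical_quality_root
        )
    return o


def _ensure_roles(o: Ontology, expr: ClassExpression, registry: TemplateRegistry):
    from .dl import roles_in

    for r in roles_in(expr):
        o.roles.setdefault(r, RoleDeclaration(id=r))


def disambiguated_expand(rule: DisambiguationRule, filler: ClassExpression) -> ClassExpression:
    """Disjunction over all the rule's alternative expansions."""
    parts = [expand_template(t, filler) for t in rule.alternatives]
    if len(parts) == 1:
        return parts[0]
    return Or.of(*parts)


def assign_upper_roots(o: Ontology, root_map: Mapping[str, str]) -> Ontology:
    """Add ``SubClassOf(C, upper)`` for every named class whose identifier
    prefix appears in *root_map* (prefix-only routing; GO namespace routing
    happens during :func:`convert`)."""
    for cls, upper in root_map.items():
        if upper not in UPPER_CLASSES:
            raise ConfigError(f"{upper!r} is not an upper-level class")
    out = o.copy()
    for name in sorted(o.signature):
        target = root_map.get(_prefix(name))
        if target is not None and name not in UPPER_CLASSES:
            ax = SubClassOf(Named(name), Named(target))
            if ax not in out.provenance:
                out.add_axiom(ax, "root-map")
    return out


def add_quality_constraints(
    o: Ontology,
    process_quality_root: Optional[str],
    physical_quality_root: Optional[str],
) -> Ontology:
    """Qualities of processes must inhere in processes; qualities of
    physical objects must inhere in material objects.

    Adds ``SubClassOf(process_quality_root, inheres_in only Process)`` and
    ``SubClassOf(physical_quality_root, inheres_in only MaterialObject)``.
    Idempotent (axiom-set semantics)."""
    if process_quality_root is None or physical_quality_root is None:
        raise ConfigError("quality constraints need both quality root classes")
    for ax in (
        SubClassOf(Named(process_quality_root), Only("inheres_in", Named(PROCESS))),
        SubClassOf(Named(physical_quality_root), Only("inheres_in", Named(MATERIAL_OBJECT))),
    ):
        if ax not in o.provenance:
            o.add_axiom(ax, "quality-constraint")
    return o


# ---------------------------------------------------------------------------
# Config file I/O (YAML)
# ---------------------------------------------------------------------------


def load_config(text: str) -> ConversionConfig:
    """Read a ConversionConfig from YAML.

    Schema::

        root_map: {PATO: Quality, MA: MaterialObject, ...}
        mf_mode: function | process
        strip_asserted_isa: false
        add_quality_constraints: false
        process_quality_root: PATO:0001236
        physical_quality_root: PATO:0001237
        synonyms: {has part: has_part, ...}          # merged over defaults
        templates: {rel: "inheres_in some (part_of some ?Y)", ...}  # merged
        domain_rules: [{pattern: "results_in_*", domain: Process}]
        disambiguate: [has_input, inheres_in, ...]    # built-in rules
        disambiguation_rules:                         # custom rules
          - relation: my_rel
            alternatives: ["my_rel some ?Y", "inheres_in some (my_rel some ?Y)"]
            replacements: [null, inheres_in_my_rel]
    """
    data = yaml.safe_load(text) or {}
    registry = TemplateRegistry()
    for name, body in (data.get("templates") or {}).items():
        registry.templates[name] = template(name, body)
    if "domain_rules" in data:
        registry.domain_rules = [
            (r["pattern"], r["domain"]) for r in data["domain_rules"]
        ]
    synonyms = dict(DEFAULT_SYNONYMS)
    synonyms.update(data.get("synonyms") or {})
    rules: Dict[str, DisambiguationRule] = {}
    builtin = builtin_disambiguation_rules()
    for rel in data.get("disambiguate") or []:
        if rel not in builtin:
            raise ConfigError(f"no built-in disambiguation rule for {rel!r}")
        rules[rel] = builtin[rel]
    for spec in data.get("disambiguation_rules") or []:
        alts = [template(spec["relation"], b) for b in spec["alternatives"]]
        rules[spec["relation"]] = DisambiguationRule(
            spec["relation"], alts, list(spec["replacements"])
        )
    return ConversionConfig(
        registry=registry,
        root_map=dict(data.get("root_map") or {}),
        mf_mode=data.get("mf_mode", "function"),
        synonym_map=synonyms,
        strip_asserted_isa=bool(data.get("strip_asserted_isa", False)),
        add_quality_constraints=bool(data.get("add_quality_constraints", False)),
        process_quality_root=data.get("process_quality_root"),
        physical_quality_root=data.get("physical_quality_root"),
        disambiguation=rules,
    )


def dump_config(cfg: ConversionConfig) -> str:
    data = {
        "root_map": dict(cfg.root_map),
        "mf_mode": cfg.mf_mode,
        "strip_asserted_isa": cfg.strip_asserted_isa,
        "add_quality_constraints": cfg.add_quality_constraints,
    }
    if cfg.process_quality_root:
        data["process_quality_root"] = cfg.process_quality_root
    if cfg.physical_quality_root:
        data["physical_quality_root"] = cfg.physical_quality_root
    extra_syn = {k: v for k, v in cfg.synonym_map.items()
                 if DEFAULT_SYNONYMS.get(k) != v}
    if extra_syn:
        data["synonyms"] = extra_syn
    base = builtin_templates()
    extra_tpl = {
        name: to_manchester(t.body)
        for name, t in cfg.registry.templates.items()
        if base.get(name) is None or base[name].body != t.body
    }
    if extra_tpl:
        data["templates"] = extra_tpl
    builtin = builtin_disambiguation_rules()
    std = [r for r in cfg.disambiguation if cfg.disambiguation[r] is builtin.get(r)
           or (r in builtin and cfg.disambiguation[r] == builtin[r])]
    if std:
        data["disambiguate"] = sorted(std)
    custom = [
        {
            "relation": rule.relation,
            "alternatives": [to_manchester(t.body) for t in rule.alternatives],
            "replacements": list(rule.replacement_names),
        }
        for rel, rule in cfg.disambiguation.items()
        if rel not in std
    ]
    if custom:
        data["disambiguation_rules"] = custom
    return yaml.safe_dump(data, sort_keys=True)
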