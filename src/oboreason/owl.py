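"""OWL 2 functional-style syntax export.

Lets the converted axiom set be checked with an external OWL reasoner
(HermiT, Pellet, FaCT++ via Protégé or the OWL API).  Identifiers are
wrapped into ``urn:obo:`` IRIs, which keeps OBO-style identifiers (with
their colons) legal.
"""

from __future__ import annotations

from typing import List

from .dl import (
    And,
    Axiom,
    DisjointClasses,
    EquivalentClasses,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    Some,
    SubClassOf,
    _Bottom,
    _Top,
)


def _iri(name: str) -> str:
    return f"<urn:obo:{name}>"


def _class_expr(e) -> str:
    if isinstance(e, Named):
        return _iri(e.name)
    if isinstance(e, _Top):
        return "owl:Thing"
    if isinstance(e, _Bottom):
        return "owl:Nothing"
    if isinstance(e, Not):
        return f"ObjectComplementOf({_class_expr(e.arg)})"
    if isinstance(e, And):
        return "ObjectIntersectionOf(" + " ".join(map(_class_expr, e.args)) + ")"
    if isinstance(e, Or):
        return "ObjectUnionOf(" + " ".join(map(_class_expr, e.args)) + ")"
    if isinstance(e, Some):
        return f"ObjectSomeValuesFrom({_iri(e.role)} {_class_expr(e.filler)})"
    if isinstance(e, Only):
        return f"ObjectAllValuesFrom({_iri(e.role)} {_class_expr(e.filler)})"
    raise TypeError(f"not a class expression: {e!r}")


def _axiom(ax: Axiom) -> str:
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({_class_expr(ax.sub)} {_class_expr(ax.sup)})"
    if isinstance(ax, EquivalentClasses):
        return f"EquivalentClasses({_class_expr(ax.a)} {_class_expr(ax.b)})"
    if isinstance(ax, DisjointClasses):
        return "DisjointClasses(" + " ".join(map(_class_expr, ax.members)) + ")"
    raise TypeError(f"not an axiom: {ax!r}")


def export_functional(o: Ontology, ontology_iri: str = "urn:obo:converted") -> str:
    lines: List[str] = [
        "Prefix(owl:=<http://www.w3.org/2002/07/owl#>)",
        f"Ontology(<{ontology_iri}>",
    ]
    for name in sorted(o.signature):
        lines.append(f"Declaration(Class({_iri(name)}))")
    for rid in sorted(o.roles):
        lines.append(f"Declaration(ObjectProperty({_iri(rid)}))")
    for rid in sorted(o.roles):
        d = o.roles[rid]
        p = _iri(rid)
        if d.transitive:
            lines.append(f"TransitiveObjectProperty({p})")
        if d.reflexive:
            lines.append(f"ReflexiveObjectProperty({p})")
        if d.symmetric:
            lines.append(f"SymmetricObjectProperty({p})")
        if d.functional:
            lines.append(f"FunctionalObjectProperty({p})")
        if d.inverse is not None and rid < d.inverse:
            lines.append(f"InverseObjectProperties({p} {_iri(d.inverse)})")
        for sup in sorted(d.super_roles):
            lines.append(f"SubObjectPropertyOf({p} {_iri(sup)})")
        if d.domain is not None:
            lines.append(f"ObjectPropertyDomain({p} {_class_expr(d.domain)})")
        if d.range is not None:
            lines.append(f"ObjectPropertyRange({p} {_class_expr(d.range)})")
    for ax in o.axioms:
        lines.append(_axiom(ax))
    lines.append(")")
    return "\n".join(lines) + "\n"
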