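"""Semi-automatic repair of ambiguous relation use.

An ambiguously used relation (say ``has_central_participant``, a
process-to-material relation that phenotype definitions also apply to
qualities) is expanded to the *disjunction* of its candidate readings
during conversion.  Because the wrong reading contradicts the rest of the
class definition, the reasoner can eliminate it: substituting each
alternative in turn and testing the class's satisfiability resolves every
use to its intended or unintended meaning.  Resolved unintended uses are
then rewritten in the source document to a new composite relation
(``inheres_in_has_central_participant`` and friends), after which strict
conversion no longer produces the ambiguity-caused contradictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .convert import (
    ConversionConfig,
    DisambiguationRule,
    disambiguated_expand,
    expand_template,
)
from .dl import (
    And,
    DisjointClasses,
    EquivalentClasses,
    Named,
    Ontology,
    SubClassOf,
    replace_subexpression,
)
from .obo import OboDocument, TypedefFrame
from .reasoner import Reasoner, Verdict

INTENDED = "intended"
UNINTENDED = "unintended"
AMBIGUOUS = "ambiguous"
NEITHER = "neither"
UNDECIDED = "undecided"

STATUSES = (INTENDED, UNINTENDED, AMBIGUOUS, NEITHER, UNDECIDED)


@dataclass
class ResolvedUse:
    class_id: str
    relation: str
    filler: str
    status: str
    #: index of the single satisfiable alternative (0 = intended) when resolved
    alternative: Optional[int] = None


@dataclass
class ResolutionReport:
    relation: str
    uses: List[ResolvedUse] = field(default_factory=list)

    def counts(self) -> Dict[str, int]:
        out = {s: 0 for s in STATUSES}
        for u in self.uses:
            out[u.status] += 1
        return out

    def by_status(self, status: str) -> List[ResolvedUse]:
        return [u for u in self.uses if u.status == status]


def resolve_uses(
    o: Ontology,
    rule: DisambiguationRule,
    combination_cap: int = 64,
    **reasoner_kw,
) -> ResolutionReport:
    """Resolve every recorded use of ``rule.relation`` in *o*.

    The ontology must have been converted with disambiguated expansion for
    the rule's relation (its use sites are recorded on
    ``o.ambiguous_uses``).  For each use, each alternative reading is
    substituted for the disjunction in the class's own axioms — other
    classes keep their disjunctions — and the class's satisfiability is
    tested.  Classes with several ambiguous uses are tested over the
    cross-product of alternative assignments, capped at
    ``combination_cap`` combinations (beyond the cap the uses are flagged
    undecided).  Exactly one satisfiable alternative resolves the use;
    all-satisfiable is *ambiguous*, none *neither*.
    """
    report = ResolutionReport(relation=rule.relation)
    uses = [
        (cls, rel, filler, expr)
        for cls, rel, filler, expr in o.ambiguous_uses
        if rel == rule.relation
    ]
    by_class: Dict[str, List[Tuple[str, object]]] = {}
    for cls, rel, filler, expr in uses:
        sites = by_class.setdefault(cls, [])
        if (filler, expr) not in sites:
            sites.append((filler, expr))

    n_alt = len(rule.alternatives)
    for cls in sorted(by_class):
        sites = by_class[cls]
        k = len(sites)
        if n_alt ** k > combination_cap:
            for filler, _ in sites:
                report.uses.append(
                    ResolvedUse(cls, rule.relation, filler, UNDECIDED, None)
                )
            continue
        # possible[i] = set of alternatives participating in some satisfiable
        # assignment for site i
        possible: List[Set[int]] = [set() for _ in range(k)]
        saw_undecided = False
        for assignment in itertools.product(range(n_alt), repeat=k):
            o2 = _substituted(o, cls, sites, assignment, rule)
            v = Reasoner(o2, **reasoner_kw).check(Named(cls))
            if v is Verdict.UNDECIDED:
                saw_undecided = True
            elif v is Verdict.SAT:
                for i, a in enumerate(assignment):
                    possible[i].add(a)
        for i, (filler, _) in enumerate(sites):
            if saw_undecided:
                status, alt = UNDECIDED, None
            elif len(possible[i]) == 1:
                alt = next(iter(possible[i]))
                status = INTENDED if alt == 0 else UNINTENDED
            elif len(possible[i]) == 0:
                status, alt = NEITHER, None
            else:
                status, alt = AMBIGUOUS, None
            report.uses.append(ResolvedUse(cls, rule.relation, filler, status, alt))
    return report


def _substituted(
    o: Ontology,
    cls: str,
    sites: List[Tuple[str, object]],
    assignment: Sequence[int],
    rule: DisambiguationRule,
) -> Ontology:
    """Copy of *o* with the class's disjunctive use sites replaced by the
    assigned alternatives."""
    target = Named(cls)
    out = o.copy()
    new_axioms = []
    for ax in out.axioms:
        if isinstance(ax, SubClassOf) and ax.sub == target:
            sup = ax.sup
            for (filler, orexpr), a in zip(sites, assignment):
                repl = expand_template(rule.alternatives[a], Named(filler))
                sup = replace_subexpression(sup, orexpr, repl)
            new_ax = SubClassOf(ax.sub, sup)
        elif isinstance(ax, EquivalentClasses) and ax.a == target:
            b = ax.b
            for (filler, orexpr), a in zip(sites, assignment):
                repl = expand_template(rule.alternatives[a], Named(filler))
                b = replace_subexpression(b, orexpr, repl)
            new_ax = EquivalentClasses(ax.a, b)
        else:
            new_ax = ax
        new_axioms.append(new_ax)
        out.provenance.setdefault(new_ax, out.provenance.get(ax, "substituted"))
    out.axioms = new_axioms
    return out


def rewrite_resolved(
    doc: OboDocument,
    reports: Sequence[ResolutionReport],
    rules: Mapping[str, DisambiguationRule],
) -> OboDocument:
    """Rewrite resolved unintended uses to their composite relation.

    Each use resolved *unintended* has its relation identifier replaced by
    the rule's replacement name for the resolved alternative, in both
    ``relationship:`` and ``intersection_of:`` lines.  A ``[Typedef]``
    stanza is added for each newly introduced relation.  Uses that are
    ambiguous, neither or undecided are left untouched and listed in the
    document's warnings.
    """
    out = doc.copy()
    new_relations: Set[str] = set()
    for report in reports:
        rule = rules[report.relation]
        for use in report.uses:
            if use.status in (AMBIGUOUS, NEITHER, UNDECIDED):
                out.warnings.append(
                    f"unresolved {use.status} use of {use.relation} "
                    f"on {use.class_id} (filler {use.filler}); not rewritten"
                )
                continue
            if use.status == INTENDED or use.alternative in (None, 0):
                continue
            replacement = rule.replacement_names[use.alternative]
            if replacement is None:
                continue
            frame = out.term(use.class_id)
            frame.relationship = [
                (replacement, tgt) if rel == use.relation and tgt == use.filler
                else (rel, tgt)
                for rel, tgt in frame.relationship
            ]
            frame.intersection_of = [
                (replacement, tgt)
                if rel == use.relation and tgt == use.filler
                else (rel, tgt)
                for rel, tgt in frame.intersection_of
            ]
            new_relations.add(replacement)
    existing = out.typedef_ids()
    for rid in sorted(new_relations - existing):
        out.typedefs.append(TypedefFrame(id=rid, name=rid.replace("_", " ")))
    return out


def compare_unsat(
    before: Ontology, after: Ontology, **reasoner_kw
) -> Tuple[Set[str], Set[str]]:
    """(contradictions removed, contradictions remaining) between two
    converted ontologies (e.g. strict vs disambiguated-and-rewritten)."""
    b_unsat, b_und = Reasoner(before, **reasoner_kw).unsatisfiable_report()
    a_unsat, a_und = Reasoner(after, **reasoner_kw).unsatisfiable_report()
    removed = b_unsat - a_unsat
    remaining = a_unsat
    return removed, remaining
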