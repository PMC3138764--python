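"""Tableau satisfiability checking, classification and queries.

Decides class-expression satisfiability over the fragment the conversion
step emits: ALC plus role hierarchies, inverse roles, transitive roles,
functional roles and role domain/range constraints.  A completion graph of
labelled nodes is expanded under the usual rules:

* conjunctions are decomposed; disjunctions branch with chronological
  backtracking (disjuncts whose complement is already in the label are
  pruned, and a single live disjunct is propagated deterministically);
* existential restrictions create role successors (role-hierarchy aware);
* universal restrictions propagate along neighbours, with the extra
  propagation step for transitive sub-roles;
* functional roles merge surplus neighbours (oldest node wins);
* role domain/range constraints fire directly on edges;
* axioms with a named class on the left-hand side (possibly inside a
  conjunction) are applied lazily by unfolding/absorption; the rare
  remaining general inclusions are internalized into every node label.

Termination is enforced by pairwise (equality) blocking plus hard resource
caps; exceeding a cap yields an explicit *undecided* verdict, never a
silent answer.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .dl import (
    And,
    Bottom,
    ClassExpression,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    RoleDeclaration,
    Some,
    SubClassOf,
    Top,
    _Bottom,
    _Top,
    _sort_key,
    complement,
    nnf,
    normalize_axioms,
    super_roles_closure,
)


class Verdict(enum.Enum):
    SAT = "satisfiable"
    UNSAT = "unsatisfiable"
    UNDECIDED = "undecided"


class Undecided(Exception):
    """Raised when a resource cap is hit before a verdict is reached."""


class _Clash(Exception):
    pass


# ---------------------------------------------------------------------------
# Completion graph state
# ---------------------------------------------------------------------------


class _State:
    __slots__ = ("labels", "succ", "parent", "parent_roles", "next_id", "alive")

    def __init__(self):
        self.labels: Dict[int, Set[ClassExpression]] = {}
        # succ[src][tgt] = set of role ids
        self.succ: Dict[int, Dict[int, Set[str]]] = {}
        self.parent: Dict[int, Optional[int]] = {}
        self.parent_roles: Dict[int, FrozenSet[str]] = {}
        self.next_id = 0
        self.alive: Set[int] = set()

    def clone(self) -> "_State":
        st = _State.__new__(_State)
        st.labels = {n: set(l) for n, l in self.labels.items()}
        st.succ = {n: {t: set(r) for t, r in d.items()} for n, d in self.succ.items()}
        st.parent = dict(self.parent)
        st.parent_roles = dict(self.parent_roles)
        st.next_id = self.next_id
        st.alive = set(self.alive)
        return st

    def new_node(self, parent: Optional[int], roles: Iterable[str]) -> int:
        n = self.next_id
        self.next_id += 1
        self.labels[n] = set()
        self.succ[n] = {}
        self.parent[n] = parent
        self.parent_roles[n] = frozenset(roles)
        self.alive.add(n)
        if parent is not None:
            self.succ[parent].setdefault(n, set()).update(roles)
        return n

    def add_edge(self, src: int, tgt: int, role: str) -> bool:
        roles = self.succ[src].setdefault(tgt, set())
        if role in roles:
            return False
        roles.add(role)
        return True


# ---------------------------------------------------------------------------
# Reasoner
# ---------------------------------------------------------------------------


@dataclass
class ClassificationIndex:
    """Subsumption hierarchy over satisfiable classes.

    ``equivalents`` maps each satisfiable class to its (mutual-subsumption)
    equivalence group; ``direct_supers`` is the transitive reduction of the
    subsumption order over group representatives.  Unsatisfiable classes —
    exactly those equivalent to Nothing — are listed separately.
    """

    equivalents: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    direct_supers: Dict[str, Set[str]] = field(default_factory=dict)
    unsatisfiable: Set[str] = field(default_factory=set)
    undecided: Set[str] = field(default_factory=set)

    def ancestors(self, name: str) -> Set[str]:
        out: Set[str] = set()
        frontier = list(self.direct_supers.get(name, ()))
        while frontier:
            s = frontier.pop()
            if s not in out:
                out.add(s)
                frontier.extend(self.direct_supers.get(s, ()))
        # expand representatives to full equivalence groups
        full: Set[str] = set()
        for s in out:
            full |= set(self.equivalents.get(s, {s}))
        return full


class Reasoner:
    """Satisfiability/subsumption engine over one ontology.

    Preprocessing (normalization, absorption, role closures) happens once in
    the constructor; individual checks are then cheap to repeat.
    """

    def __init__(
        self,
        ontology: Ontology,
        node_limit: int = 100_000,
        branch_limit: int = 10_000,
    ):
        self.ontology = ontology
        self.node_limit = node_limit
        self.branch_limit = branch_limit
        self._prepare(normalize_axioms(ontology))

    # -- preprocessing ------------------------------------------------------

    def _prepare(self, norm: Ontology) -> None:
        self.unfold: Dict[str, List[ClassExpression]] = {}
        self.tc: List[ClassExpression] = []
        for ax in norm.axioms:
            assert isinstance(ax, SubClassOf)
            sup_n = nnf(ax.sup)
            sub = ax.sub
            if isinstance(sub, Named):
                self.unfold.setdefault(sub.name, []).append(sup_n)
            elif isinstance(sub, _Top):
                self.tc.append(sup_n)
            elif isinstance(sub, And) and any(isinstance(a, Named) for a in sub.args):
                # absorption: And(A, R...) ⊑ D  ~~>  A ⊑ ¬R ⊔ D
                named = next(a for a in sub.args if isinstance(a, Named))
                rest = And.of(*(a for a in sub.args if a is not named))
                self.unfold.setdefault(named.name, []).append(
                    nnf(Or.of(Not(rest), ax.sup))
                )
            else:
                self.tc.append(nnf(Or.of(Not(sub), ax.sup)))
        # dedupe, deterministic order
        for k in self.unfold:
            self.unfold[k] = sorted(set(self.unfold[k]), key=_sort_key)
        self.tc = sorted(set(self.tc), key=_sort_key)

        roles = norm.roles
        self.inv: Dict[str, Optional[str]] = {}
        self.supers: Dict[str, FrozenSet[str]] = {}
        self.transitive: Set[str] = set()
        self.functional: Set[str] = set()
        self.reflexive: Set[str] = set()
        self.domain: Dict[str, ClassExpression] = {}
        self.range: Dict[str, ClassExpression] = {}
        for r, decl in roles.items():
            self.inv[r] = decl.inverse if decl.inverse else (r if decl.symmetric else None)
            self.supers[r] = frozenset(super_roles_closure(norm, r))
            if decl.transitive:
                self.transitive.add(r)
            if decl.functional:
                self.functional.add(r)
            if decl.reflexive:
                self.reflexive.add(r)
            if decl.domain is not None:
                self.domain[r] = nnf(decl.domain)
            if decl.range is not None:
                self.range[r] = nnf(decl.range)

    def _supers(self, r: str) -> FrozenSet[str]:
        s = self.supers.get(r)
        return s if s is not None else frozenset({r})

    # -- public API ---------------------------------------------------------

    def check(self, e: ClassExpression) -> Verdict:
        """Three-valued satisfiability check of *e* w.r.t. the ontology."""
        self._nodes_made = 0
        self._branches = 0
        st = _State()
        root = st.new_node(None, ())
        try:
            self._add(st, root, nnf(e))
            self._init_node(st, root)
        except _Clash:
            return Verdict.UNSAT
        try:
            return Verdict.SAT if self._run(st) else Verdict.UNSAT
        except (Undecided, RecursionError):
            return Verdict.UNDECIDED

    def is_satisfiable(self, e: ClassExpression) -> bool:
        v = self.check(e)
        if v is Verdict.UNDECIDED:
            raise Undecided(f"resource cap exceeded while checking {e!r}")
        return v is Verdict.SAT

    def subsumes(self, sup: ClassExpression, sub: ClassExpression) -> bool:
        """True iff every instance of *sub* must be an instance of *sup*."""
        return not self.is_satisfiable(And.of(sub, complement(sup)))

    def unsatisfiable_classes(self) -> Set[str]:
        unsat, undecided = self.unsatisfiable_report()
        if undecided:
            raise Undecided(f"undecided classes: {sorted(undecided)}")
        return unsat

    def unsatisfiable_report(self) -> Tuple[Set[str], Set[str]]:
        """(unsatisfiable classes, classes the caps left undecided)."""
        unsat: Set[str] = set()
        undecided: Set[str] = set()
        for name in sorted(self.ontology.signature):
            v = self.check(Named(name))
            if v is Verdict.UNSAT:
                unsat.add(name)
            elif v is Verdict.UNDECIDED:
                undecided.add(name)
        return unsat, undecided

    def query_subclasses(
        self, e: ClassExpression, include_unsatisfiable: bool = False
    ) -> Set[str]:
        """Named classes subsumed by *e* (Nothing-equivalent ones excluded
        unless requested)."""
        out: Set[str] = set()
        for name in sorted(self.ontology.signature):
            if not self.subsumes(e, Named(name)):
                continue
            if include_unsatisfiable or self.is_satisfiable(Named(name)):
                out.add(name)
        return out

    def classify(self) -> ClassificationIndex:
        """Full classification: equivalence groups and direct super-classes."""
        idx = ClassificationIndex()
        sat: List[str] = []
        for name in sorted(self.ontology.signature):
            v = self.check(Named(name))
            if v is Verdict.UNSAT:
                idx.unsatisfiable.add(name)
            elif v is Verdict.UNDECIDED:
                idx.undecided.add(name)
            else:
                sat.append(name)
        g = nx.DiGraph()
        g.add_nodes_from(sat)
        for a in sat:
            for b in sat:
                if a != b and self.subsumes(Named(b), Named(a)):
                    g.add_edge(a, b)  # a ⊑ b
        # equivalence groups = strongly connected components
        comp = list(nx.strongly_connected_components(g))
        rep = {}
        for group in comp:
            r = min(group)
            for m in group:
                rep[m] = r
                idx.equivalents[m] = frozenset(group)
        dag = nx.DiGraph()
        dag.add_nodes_from({rep[a] for a in sat})
        for a, b in g.edges():
            if rep[a] != rep[b]:
                dag.add_edge(rep[a], rep[b])
        reduced = nx.transitive_reduction(dag)
        for name in sat:
            idx.direct_supers[name] = set(reduced.successors(rep[name]))
        return idx

    def justify(self, class_id: str) -> List:
        """A subset-minimal axiom set keeping *class_id* unsatisfiable.

        Deletion-based shrinking over the ontology's axiom list (one
        justification, deterministic).  Raises ValueError on satisfiable
        input; the role box is kept fixed.
        """
        if self.is_satisfiable(Named(class_id)):
            raise ValueError(f"{class_id} is satisfiable; nothing to justify")
        kept = list(self.ontology.axioms)
        i = 0
        while i < len(kept):
            trial = kept[:i] + kept[i + 1:]
            if not self._subset_satisfiable(trial, class_id):
                kept = trial
            else:
                i += 1
        return kept

    def _subset_satisfiable(self, axioms: List, class_id: str) -> bool:
        sub = Ontology(
            signature=set(self.ontology.signature),
            roles={r: d.copy() for r, d in self.ontology.roles.items()},
        )
        for ax in axioms:
            sub.add_axiom(ax, self.ontology.provenance.get(ax, "subset"))
        r = Reasoner(sub, self.node_limit, self.branch_limit)
        return r.is_satisfiable(Named(class_id))

    # -- tableau machinery --------------------------------------------------

    def _add(self, st: _State, n: int, e: ClassExpression) -> bool:
        label = st.labels[n]
        if e in label:
            return False
        if isinstance(e, _Top):
            return False
        label.add(e)
        if isinstance(e, _Bottom):
            raise _Clash()
        if isinstance(e, Named) and Not(e) in label:
            raise _Clash()
        if isinstance(e, Not) and e.arg in label:
            raise _Clash()
        return True

    def _init_node(self, st: _State, n: int) -> None:
        for e in self.tc:
            self._add(st, n, e)
        for r in self.reflexive:
            st.add_edge(n, n, r)

    def _neighbours(self, st: _State, n: int, role: str) -> List[int]:
        """Targets reachable from n via `role` (role hierarchy + inverses)."""
        out = []
        for t, rs in st.succ[n].items():
            if t in st.alive and any(role in self._supers(s) for s in rs):
                out.append(t)
        for x in st.alive:
            rs = st.succ[x].get(n)
            if rs and x != n:
                for s in rs:
                    si = self.inv.get(s)
                    if si is not None and role in self._supers(si):
                        out.append(x)
                        break
        return sorted(set(out))

    def _edge_roles_between(self, st: _State, n: int, t: int) -> Set[str]:
        """All roles (direct and via inverses) along which t is a neighbour of n."""
        out: Set[str] = set()
        rs = st.succ[n].get(t)
        if rs:
            for s in rs:
                out |= self._supers(s)
        back = st.succ[t].get(n)
        if back:
            for s in back:
                si = self.inv.get(s)
                if si is not None:
                    out |= self._supers(si)
        return out

    def _blocked(self, st: _State, n: int) -> bool:
        """Directly or indirectly blocked under pairwise (equality) blocking."""
        seen = set()
        m = n
        while m is not None and m not in seen:
            seen.add(m)
            if self._directly_blocked(st, m):
                return True
            m = st.parent.get(m)
        return False

    def _directly_blocked(self, st: _State, y: int) -> bool:
        yp = st.parent.get(y)
        if yp is None or yp not in st.alive:
            return False
        ly, lyp = st.labels[y], st.labels[yp]
        ery = frozenset(st.succ[yp].get(y, ()))
        for x in sorted(st.alive):
            if x >= y:
                break
            xp = st.parent.get(x)
            if xp is None or xp not in st.alive:
                continue
            if (
                st.labels[x] == ly
                and st.labels[xp] == lyp
                and frozenset(st.succ[xp].get(x, ())) == ery
                and not self._directly_blocked(st, x)
            ):
                return True
        return False

    def _apply_deterministic(self, st: _State) -> bool:
        """One pass of all non-branching rules; True if anything changed."""
        changed = False
        for n in sorted(st.alive):
            if n not in st.alive:
                continue
            label = st.labels[n]
            for e in sorted(label, key=_sort_key):
                if n not in st.alive or e not in st.labels[n]:
                    continue
                if isinstance(e, And):
                    for a in e.args:
                        changed |= self._add(st, n, a)
                elif isinstance(e, Named):
                    for d in self.unfold.get(e.name, ()):
                        changed |= self._add(st, n, d)
                elif isinstance(e, Or):
                    # unit propagation; full clash handled here too
                    live = [a for a in e.args if complement(a) not in st.labels[n]]
                    if any(a in st.labels[n] for a in live):
                        continue
                    if not live:
                        raise _Clash()
                    if len(live) == 1:
                        changed |= self._add(st, n, live[0])
                elif isinstance(e, Only):
                    for t in self._neighbours(st, n, e.role):
                        changed |= self._add(st, t, e.filler)
                        if n not in st.alive:
                            break
                    if n not in st.alive:
                        continue
                    for q in self.transitive:
                        if e.role in self._supers(q):
                            for t in self._neighbours(st, n, q):
                                changed |= self._add(st, t, Only(q, e.filler))
                                if n not in st.alive:
                                    break
            if n not in st.alive:
                changed = True
                continue
            # domain/range on edges
            for t in list(st.succ[n].keys()):
                if t not in st.alive or n not in st.alive:
                    continue
                for s in list(st.succ[n].get(t, ())):
                    for r in self._supers(s):
                        d = self.domain.get(r)
                        if d is not None:
                            changed |= self._add(st, n, d)
                        rng = self.range.get(r)
                        if rng is not None:
                            changed |= self._add(st, t, rng)
                    si = self.inv.get(s)
                    if si is not None:
                        for r in self._supers(si):
                            d = self.domain.get(r)
                            if d is not None:
                                changed |= self._add(st, t, d)
                            rng = self.range.get(r)
                            if rng is not None:
                                changed |= self._add(st, n, rng)
            # functional merging
            for f in self.functional:
                if n not in st.alive:
                    break
                nb = self._neighbours(st, n, f)
                nb = [t for t in nb if t != n]
                if len(nb) >= 2:
                    self._merge(st, nb[0], nb[1])
                    changed = True
        return changed

    def _merge(self, st: _State, keep: int, drop: int) -> None:
        """Merge node *drop* into older node *keep* (label union, edges
        redirected, children re-parented)."""
        if keep == drop:
            return
        for e in list(st.labels[drop]):
            self._add(st, keep, e)
        for t, rs in list(st.succ[drop].items()):
            tgt = keep if t == drop else t
            if tgt in st.alive or tgt == keep:
                st.succ[keep].setdefault(tgt, set()).update(rs)
        for x in list(st.alive):
            if x == drop:
                continue
            rs = st.succ[x].pop(drop, None)
            if rs:
                st.succ[x].setdefault(keep, set()).update(rs)
        for x in list(st.alive):
            if st.parent.get(x) == drop:
                st.parent[x] = keep
        st.alive.discard(drop)
        del st.labels[drop]
        del st.succ[drop]

    def _find_or(self, st: _State):
        best = None
        for n in sorted(st.alive):
            for e in sorted(st.labels[n], key=_sort_key):
                if isinstance(e, Or):
                    live = [a for a in e.args if complement(a) not in st.labels[n]]
                    if any(a in st.labels[n] for a in live):
                        continue
                    if best is None or len(live) < len(best[2]):
                        best = (n, e, live)
            if best is not None and len(best[2]) == 2:
                return best
        return best

    def _find_some(self, st: _State):
        for n in sorted(st.alive):
            pending = [
                e for e in sorted(st.labels[n], key=_sort_key)
                if isinstance(e, Some)
                and not any(
                    e.filler in st.labels[t] for t in self._neighbours(st, n, e.role)
                )
            ]
            if pending and not self._blocked(st, n):
                return n, pending[0]
        return None

    def _run(self, st: _State) -> bool:
        while True:
            try:
                while self._apply_deterministic(st):
                    pass
            except _Clash:
                return False
            choice = self._find_or(st)
            if choice is not None:
                n, e, live = choice
                # heuristic: try non-Named disjuncts first — for absorbed
                # definition axioms (¬rest ⊔ DefinedClass) the complement
                # branch usually survives, while asserting the defined class
                # cascades through its whole definition
                ordered = sorted(live, key=lambda a: (isinstance(a, Named), _sort_key(a)))
                for d in ordered:
                    self._branches += 1
                    if self._branches > self.branch_limit:
                        raise Undecided("branch limit exceeded")
                    st2 = st.clone()
                    try:
                        self._add(st2, n, d)
                    except _Clash:
                        continue
                    if self._run(st2):
                        return True
                return False
            gen = self._find_some(st)
            if gen is None:
                return True
            n, e = gen
            self._nodes_made += 1
            if self._nodes_made > self.node_limit:
                raise Undecided("node limit exceeded")
            try:
                m = st.new_node(n, (e.role,))
                self._add(st, m, e.filler)
                self._init_node(st, m)
            except _Clash:
                return False


# ---------------------------------------------------------------------------
# Module-level convenience wrappers
# ---------------------------------------------------------------------------


def is_satisfiable(o: Ontology, e: ClassExpression, **kw) -> bool:
    return Reasoner(o, **kw).is_satisfiable(e)


def unsatisfiable_classes(o: Ontology, **kw) -> Set[str]:
    return Reasoner(o, **kw).unsatisfiable_classes()


def subsumes(o: Ontology, sup: ClassExpression, sub: ClassExpression, **kw) -> bool:
    return Reasoner(o, **kw).subsumes(sup, sub)


def classify(o: Ontology, **kw) -> ClassificationIndex:
    return Reasoner(o, **kw).classify()


def query_subclasses(
    o: Ontology, e: ClassExpression, include_unsatisfiable: bool = False, **kw
) -> Set[str]:
    return Reasoner(o, **kw).query_subclasses(e, include_unsatisfiable)


def justify(o: Ontology, class_id: str, **kw) -> List:
    return Reasoner(o, **kw).justify(class_id)
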