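"""Core description-logic representation.

The fragment is ALC extended with role hierarchies, inverse roles,
transitive roles, functional roles and role domain/range axioms — exactly
what is needed to expand class-class relations in biomedical ontologies
into class expressions and to detect contradictory definitions.  No
nominals, no datatypes, no cardinality restrictions beyond functionality.

Class expressions are immutable and hashable; ``And``/``Or`` arguments are
flattened, de-duplicated and kept in a canonical order at construction
time, so structural equality is order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------


class ClassExpression:
    """Base class for all class expressions (abstract)."""

    __slots__ = ()

    def __and__(self, other: "ClassExpression") -> "ClassExpression":
        return And.of(self, other)

    def __or__(self, other: "ClassExpression") -> "ClassExpression":
        return Or.of(self, other)

    def __invert__(self) -> "ClassExpression":
        return Not(self)


@dataclass(frozen=True, slots=True)
class Named(ClassExpression):
    """A named (atomic) class, identified by its ontology identifier."""

    name: str

    def __repr__(self) -> str:
        return f"Named({self.name!r})"


@dataclass(frozen=True, slots=True)
class _Top(ClassExpression):
    def __repr__(self) -> str:
        return "Top"


@dataclass(frozen=True, slots=True)
class _Bottom(ClassExpression):
    def __repr__(self) -> str:
        return "Bottom"


#: The universal class (owl:Thing).
Top = _Top()
#: The empty class (owl:Nothing).
Bottom = _Bottom()


@dataclass(frozen=True, slots=True)
class Not(ClassExpression):
    arg: ClassExpression

    def __repr__(self) -> str:
        return f"Not({self.arg!r})"


def _sort_key(e: ClassExpression) -> tuple:
    # Deterministic total order on expressions for canonical And/Or argument
    # order.  Cheap structural key; ties broken by repr.
    return (type(e).__name__, repr(e))


def _flatten(cls, args: Iterable[ClassExpression], absorbing, neutral) -> tuple:
    out = []
    for a in args:
        if isinstance(a, cls):
            out.extend(a.args)
        elif a == absorbing:
            return (absorbing,)
        elif a == neutral:
            continue
        else:
            out.append(a)
    seen = set()
    uniq = []
    for a in sorted(out, key=_sort_key):
        if a not in seen:
            seen.add(a)
            uniq.append(a)
    return tuple(uniq)


@dataclass(frozen=True, slots=True)
class And(ClassExpression):
    """Intersection.  Use :meth:`And.of` to construct with normalization."""

    args: tuple

    @staticmethod
    def of(*args: ClassExpression) -> ClassExpression:
        flat = _flatten(And, args, Bottom, Top)
        if not flat:
            return Top
        if len(flat) == 1:
            return flat[0]
        return And(flat)

    def __repr__(self) -> str:
        return f"And({', '.join(map(repr, self.args))})"


@dataclass(frozen=True, slots=True)
class Or(ClassExpression):
    """Union.  Use :meth:`Or.of` to construct with normalization."""

    args: tuple

    @staticmethod
    def of(*args: ClassExpression) -> ClassExpression:
        flat = _flatten(Or, args, Top, Bottom)
        if not flat:
            return Bottom
        if len(flat) == 1:
            return flat[0]
        return Or(flat)

    def __repr__(self) -> str:
        return f"Or({', '.join(map(repr, self.args))})"


@dataclass(frozen=True, slots=True)
class Some(ClassExpression):
    """Existential restriction: ``role some filler``."""

    role: str
    filler: ClassExpression

    def __repr__(self) -> str:
        return f"Some({self.role!r}, {self.filler!r})"


@dataclass(frozen=True, slots=True)
class Only(ClassExpression):
    """Universal restriction: ``role only filler``."""

    role: str
    filler: ClassExpression

    def __repr__(self) -> str:
        return f"Only({self.role!r}, {self.filler!r})"


def nnf(e: ClassExpression) -> ClassExpression:
    """Negation normal form: push ``Not`` inward onto named classes.

    Idempotent; also re-canonicalizes And/Or argument order.
    """
    if isinstance(e, (Named, _Top, _Bottom)):
        return e
    if isinstance(e, And):
        return And.of(*(nnf(a) for a in e.args))
    if isinstance(e, Or):
        return Or.of(*(nnf(a) for a in e.args))
    if isinstance(e, Some):
        return Some(e.role, nnf(e.filler))
    if isinstance(e, Only):
        return Only(e.role, nnf(e.filler))
    if isinstance(e, Not):
        a = e.arg
        if isinstance(a, Named):
            return e
        if a is Top or isinstance(a, _Top):
            return Bottom
        if a is Bottom or isinstance(a, _Bottom):
            return Top
        if isinstance(a, Not):
            return nnf(a.arg)
        if isinstance(a, And):
            return Or.of(*(nnf(Not(x)) for x in a.args))
        if isinstance(a, Or):
            return And.of(*(nnf(Not(x)) for x in a.args))
        if isinstance(a, Some):
            return Only(a.role, nnf(Not(a.filler)))
        if isinstance(a, Only):
            return Some(a.role, nnf(Not(a.filler)))
    raise TypeError(f"not a class expression: {e!r}")


def complement(e: ClassExpression) -> ClassExpression:
    """NNF of the negation of *e* (used for clash detection and subsumption)."""
    return nnf(Not(e))


def named_classes(e: ClassExpression) -> set:
    """All class identifiers occurring in *e*."""
    out: set = set()
    stack = [e]
    while stack:
        x = stack.pop()
        if isinstance(x, Named):
            out.add(x.name)
        elif isinstance(x, Not):
            stack.append(x.arg)
        elif isinstance(x, (And, Or)):
            stack.extend(x.args)
        elif isinstance(x, (Some, Only)):
            stack.append(x.filler)
    return out


def roles_in(e: ClassExpression) -> set:
    """All role identifiers occurring in *e*."""
    out: set = set()
    stack = [e]
    while stack:
        x = stack.pop()
        if isinstance(x, Not):
            stack.append(x.arg)
        elif isinstance(x, (And, Or)):
            stack.extend(x.args)
        elif isinstance(x, (Some, Only)):
            out.add(x.role)
            stack.append(x.filler)
    return out


def replace_subexpression(
    e: ClassExpression, target: ClassExpression, replacement: ClassExpression
) -> ClassExpression:
    """Structurally replace every occurrence of *target* in *e*."""
    if e == target:
        return replacement
    if isinstance(e, Not):
        return Not(replace_subexpression(e.arg, target, replacement))
    if isinstance(e, And):
        return And.of(*(replace_subexpression(a, target, replacement) for a in e.args))
    if isinstance(e, Or):
        return Or.of(*(replace_subexpression(a, target, replacement) for a in e.args))
    if isinstance(e, Some):
        return Some(e.role, replace_subexpression(e.filler, target, replacement))
    if isinstance(e, Only):
        return Only(e.role, replace_subexpression(e.filler, target, replacement))
    return e


# ---------------------------------------------------------------------------
# Roles
# ---------------------------------------------------------------------------


@dataclass
class RoleDeclaration:
    """An object property with the axioms the method needs.

    ``domain``/``range`` of ``None`` mean owl:Thing (no constraint emitted).
    """

    id: str
    transitive: bool = False
    reflexive: bool = False
    symmetric: bool = False
    functional: bool = False
    inverse: Optional[str] = None
    super_roles: set = field(default_factory=set)
    domain: Optional[ClassExpression] = None
    range: Optional[ClassExpression] = None

    def copy(self) -> "RoleDeclaration":
        return RoleDeclaration(
            id=self.id,
            transitive=self.transitive,
            reflexive=self.reflexive,
            symmetric=self.symmetric,
            functional=self.functional,
            inverse=self.inverse,
            super_roles=set(self.super_roles),
            domain=self.domain,
            range=self.range,
        )


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------


class Axiom:
    __slots__ = ()


@dataclass(frozen=True, slots=True)
class SubClassOf(Axiom):
    sub: ClassExpression
    sup: ClassExpression

    def __repr__(self) -> str:
        return f"SubClassOf({self.sub!r}, {self.sup!r})"


@dataclass(frozen=True, slots=True)
class EquivalentClasses(Axiom):
    a: ClassExpression
    b: ClassExpression

    def __repr__(self) -> str:
        return f"EquivalentClasses({self.a!r}, {self.b!r})"


@dataclass(frozen=True, slots=True)
class DisjointClasses(Axiom):
    members: tuple

    def __init__(self, members: Sequence[ClassExpression]):
        if len(members) < 2:
            raise ValueError("DisjointClasses needs at least two members")
        object.__setattr__(self, "members", tuple(members))

    def __repr__(self) -> str:
        return f"DisjointClasses({', '.join(map(repr, self.members))})"


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


class UnknownRoleError(KeyError):
    """A role identifier was looked up but never declared."""


@dataclass
class Ontology:
    """An axiom set with a role box and per-axiom provenance.

    Provenance maps each axiom to a short source tag (``file:line:tag``,
    ``upper-ontology``, ``root-map``, ...) so justifications can point back
    to the line of OBO text an axiom came from.
    """

    signature: set = field(default_factory=set)
    roles: dict = field(default_factory=dict)
    axioms: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    #: disambiguation use sites recorded by the conversion step:
    #: list of (class_id, relation_id, filler_id, Or-expression)
    ambiguous_uses: list = field(default_factory=list)
    #: identifiers referenced but never declared in any input document
    dangling: list = field(default_factory=list)

    def add_axiom(self, ax: Axiom, source: str = "unknown") -> None:
        self.axioms.append(ax)
        self.provenance.setdefault(ax, source)
        for e in _axiom_expressions(ax):
            self.signature.update(named_classes(e))
            for r in roles_in(e):
                self.roles.setdefault(r, RoleDeclaration(id=r))

    def declare_class(self, name: str) -> None:
        self.signature.add(name)

    def declare_role(self, decl: RoleDeclaration) -> None:
        self.roles[decl.id] = decl
        if decl.inverse is not None:
            inv = self.roles.setdefault(decl.inverse, RoleDeclaration(id=decl.inverse))
            inv.inverse = decl.id

    def copy(self) -> "Ontology":
        o = Ontology(
            signature=set(self.signature),
            roles={r: d.copy() for r, d in self.roles.items()},
            axioms=list(self.axioms),
            provenance=dict(self.provenance),
            ambiguous_uses=list(self.ambiguous_uses),
            dangling=list(self.dangling),
        )
        return o


def _axiom_expressions(ax: Axiom) -> tuple:
    if isinstance(ax, SubClassOf):
        return (ax.sub, ax.sup)
    if isinstance(ax, EquivalentClasses):
        return (ax.a, ax.b)
    if isinstance(ax, DisjointClasses):
        return ax.members
    raise TypeError(f"not an axiom: {ax!r}")


def normalize_axioms(o: Ontology, compile_domain_range: bool = False) -> Ontology:
    """Reduce every axiom to ``SubClassOf`` form.

    ``EquivalentClasses(a, b)`` becomes the two inclusions;
    ``DisjointClasses(m1..mn)`` becomes ``And(mi, mj) ⊑ Bottom`` for every
    pair i<j.  Provenance of derived axioms points at the original's source.

    With ``compile_domain_range`` the role box's domain/range constraints are
    additionally emitted as GCIs (``Some(r, Top) ⊑ D`` and
    ``Top ⊑ Only(r, R)``) — useful for export and for external checkers; the
    built-in reasoner applies domain/range directly from the role box.
    """
    out = Ontology(
        signature=set(o.signature),
        roles={r: d.copy() for r, d in o.roles.items()},
        ambiguous_uses=list(o.ambiguous_uses),
        dangling=list(o.dangling),
    )
    for ax in o.axioms:
        src = o.provenance.get(ax, "unknown")
        if isinstance(ax, SubClassOf):
            out.add_axiom(ax, src)
        elif isinstance(ax, EquivalentClasses):
            out.add_axiom(SubClassOf(ax.a, ax.b), src)
            out.add_axiom(SubClassOf(ax.b, ax.a), src)
        elif isinstance(ax, DisjointClasses):
            ms = ax.members
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    out.add_axiom(SubClassOf(And.of(ms[i], ms[j]), Bottom), src)
        else:
            raise TypeError(f"not an axiom: {ax!r}")
    if compile_domain_range:
        for r, decl in o.roles.items():
            if decl.domain is not None:
                out.add_axiom(SubClassOf(Some(r, Top), decl.domain), f"domain({r})")
            if decl.range is not None:
                out.add_axiom(SubClassOf(Top, Only(r, decl.range)), f"range({r})")
    return out


def super_roles_closure(o: Ontology, r: str) -> set:
    """Reflexive-transitive closure of the sub-role graph above *r*.

    Closed under inverses: the super-role of an inverse is the inverse of the
    super-role.  Declared 2-cycles (r ⊑ s, s ⊑ r) simply yield equivalent
    roles; both end up in each other's closure.
    """
    if r not in o.roles:
        raise UnknownRoleError(r)
    closure = {r}
    frontier = [r]
    while frontier:
        s = frontier.pop()
        decl = o.roles.get(s)
        if decl is None:
            continue
        nxt = set(decl.super_roles)
        # inverse closure: r ⊑ s implies inv(r) ⊑ inv(s)
        if decl.inverse is not None:
            inv_decl = o.roles.get(decl.inverse)
            if inv_decl is not None:
                for sup in inv_decl.super_roles:
                    sup_decl = o.roles.get(sup)
                    if sup_decl is not None and sup_decl.inverse is not None:
                        nxt.add(sup_decl.inverse)
        for s2 in nxt:
            if s2 not in closure:
                closure.add(s2)
                frontier.append(s2)
    return closure
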