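"""Exhaustive bounded-model satisfiability search.

An independent reference checker for the tableau reasoner: an expression is
declared satisfiable iff a model over a finite domain of at most
``max_size`` elements exists.  The search is a direct semantic encoding —
for each candidate domain size the class memberships and role edges become
propositional variables, the axioms become propositional constraints
evaluated pointwise over the domain, and a propositional SAT solver
(sympy's DPLL) looks for a model.  Nothing is shared with the tableau
implementation beyond the expression types.

On fragments with the finite-model property and small forced models (the
ALC-plus-transitive-roles fragment exercised by the random cross-check
suite) the bounded verdict is exact.  In general a "satisfiable" answer is
always sound, while an "unsatisfiable" answer means no model within the
size bound.
"""

from __future__ import annotations

import itertools
from typing import Dict, Optional

from sympy import And as SAnd, Implies, Not as SNot, Or as SOr, Symbol, false, true
from sympy.logic.boolalg import Equivalent
from sympy.logic.inference import satisfiable

from .dl import (
    And,
    ClassExpression,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    Some,
    SubClassOf,
    _Bottom,
    _Top,
    named_classes,
    normalize_axioms,
    roles_in,
)


def _class_var(name: str, i: int) -> Symbol:
    return Symbol(f"C|{name}|{i}")


def _role_var(role: str, i: int, j: int) -> Symbol:
    return Symbol(f"R|{role}|{i}|{j}")


def _encode(e: ClassExpression, i: int, d: int):
    if isinstance(e, Named):
        return _class_var(e.name, i)
    if isinstance(e, _Top):
        return true
    if isinstance(e, _Bottom):
        return false
    if isinstance(e, Not):
        return SNot(_encode(e.arg, i, d))
    if isinstance(e, And):
        return SAnd(*(_encode(a, i, d) for a in e.args))
    if isinstance(e, Or):
        return SOr(*(_encode(a, i, d) for a in e.args))
    if isinstance(e, Some):
        return SOr(*(
            SAnd(_role_var(e.role, i, j), _encode(e.filler, j, d)) for j in range(d)
        ))
    if isinstance(e, Only):
        return SAnd(*(
            Implies(_role_var(e.role, i, j), _encode(e.filler, j, d))
            for j in range(d)
        ))
    raise TypeError(f"not a class expression: {e!r}")


def _role_constraints(o: Ontology, d: int):
    """Propositional constraints for the role box over a d-element domain."""
    cons = []
    for r, decl in o.roles.items():
        if decl.transitive:
            for i, j, k in itertools.product(range(d), repeat=3):
                cons.append(
                    Implies(SAnd(_role_var(r, i, j), _role_var(r, j, k)),
                            _role_var(r, i, k))
                )
        if decl.reflexive:
            for i in range(d):
                cons.append(_role_var(r, i, i))
        if decl.symmetric:
            for i, j in itertools.product(range(d), repeat=2):
                cons.append(Implies(_role_var(r, i, j), _role_var(r, j, i)))
        if decl.functional:
            for i in range(d):
                for j, k in itertools.combinations(range(d), 2):
                    cons.append(SNot(SAnd(_role_var(r, i, j), _role_var(r, i, k))))
        if decl.inverse is not None:
            for i, j in itertools.product(range(d), repeat=2):
                cons.append(
                    Equivalent(_role_var(r, i, j), _role_var(decl.inverse, j, i))
                )
        for sup in decl.super_roles:
            for i, j in itertools.product(range(d), repeat=2):
                cons.append(Implies(_role_var(r, i, j), _role_var(sup, i, j)))
        if decl.domain is not None:
            for i, j in itertools.product(range(d), repeat=2):
                cons.append(Implies(_role_var(r, i, j), _encode(decl.domain, i, d)))
        if decl.range is not None:
            for i, j in itertools.product(range(d), repeat=2):
                cons.append(Implies(_role_var(r, i, j), _encode(decl.range, j, d)))
    return cons


def satisfiable_in_size(o: Ontology, e: ClassExpression, d: int) -> bool:
    """Is there a model of the ontology with exactly ``d`` elements in which
    *e* has an instance (at element 0)?"""
    norm = normalize_axioms(o)
    cons = [_encode(e, 0, d)]
    for ax in norm.axioms:
        assert isinstance(ax, SubClassOf)
        for i in range(d):
            cons.append(Implies(_encode(ax.sub, i, d), _encode(ax.sup, i, d)))
    cons.extend(_role_constraints(norm, d))
    formula = SAnd(*cons)
    if formula is true:
        return True
    if formula is false:
        return False
    return bool(satisfiable(formula))


def is_satisfiable_bruteforce(
    o: Ontology, e: ClassExpression, max_size: int = 4
) -> bool:
    """Bounded-model satisfiability verdict (sizes 1..max_size)."""
    for d in range(1, max_size + 1):
        if satisfiable_in_size(o, e, d):
            return True
    return False


def unsatisfiable_classes_bruteforce(o: Ontology, max_size: int = 4) -> set:
    out = set()
    for name in sorted(o.signature):
        if not is_satisfiable_bruteforce(o, Named(name), max_size):
            out.add(name)
    return out
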