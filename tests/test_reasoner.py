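"""Tableau reasoner: satisfiability, subsumption, classification, queries,
justifications, and agreement with exhaustive bounded model search."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oboreason.bruteforce import is_satisfiable_bruteforce
from oboreason.convert import ConversionConfig, convert
from oboreason.dl import (
    And,
    Bottom,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    RoleDeclaration,
    Some,
    SubClassOf,
    Top,
)
from oboreason.fixtures import random_alc_ontology, worked_example
from oboreason.reasoner import Reasoner, Undecided, Verdict

from test_dl import exprs

A, B, C = Named("A"), Named("B"), Named("C")


def _empty():
    o = Ontology()
    o.declare_role(RoleDeclaration("r"))
    o.declare_role(RoleDeclaration("s"))
    return o


class TestSatisfiability:
    def test_bottom_is_unsatisfiable(self):
        assert not Reasoner(_empty()).is_satisfiable(Bottom)

    def test_direct_contradiction(self):
        assert not Reasoner(_empty()).is_satisfiable(And.of(A, Not(A)))

    def test_fresh_names_are_unconstrained(self):
        assert Reasoner(_empty()).is_satisfiable(Some("q", Named("Fresh")))

    def test_existential_over_bottom_filler(self):
        o = _empty()
        o.add_axiom(SubClassOf(B, Bottom), "t")
        assert not Reasoner(o).is_satisfiable(Some("r", B))

    def test_universal_is_vacuously_satisfiable(self):
        o = _empty()
        o.add_axiom(SubClassOf(B, Bottom), "t")
        assert Reasoner(o).is_satisfiable(Only("r", B))

    def test_transitive_role_propagates_universal(self):
        o = _empty()
        o.roles["r"].transitive = True
        # x -r-> y -r-> z with (only r ¬A) at x and (some r some r A)
        e = And.of(Only("r", Not(A)), Some("r", Some("r", A)))
        assert not Reasoner(o).is_satisfiable(e)

    def test_role_hierarchy_feeds_universal(self):
        o = _empty()
        o.roles["s"].super_roles.add("r")
        e = And.of(Only("r", Not(A)), Some("s", A))
        assert not Reasoner(o).is_satisfiable(e)

    def test_functional_role_merges_successors(self):
        o = _empty()
        o.roles["r"].functional = True
        o.add_axiom(SubClassOf(A, Not(B)), "t")
        e = And.of(Some("r", A), Some("r", B))
        assert not Reasoner(o).is_satisfiable(e)
        o2 = _empty()
        o2.add_axiom(SubClassOf(A, Not(B)), "t")
        assert Reasoner(o2).is_satisfiable(e)

    def test_domain_constraint_fires(self):
        o = _empty()
        o.roles["r"].domain = A
        assert not Reasoner(o).is_satisfiable(And.of(Not(A), Some("r", Top)))

    def test_cyclic_axioms_terminate_via_blocking(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, Some("r", A)), "t")
        assert Reasoner(o).is_satisfiable(A)

    def test_resource_cap_yields_undecided_not_a_silent_answer(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, Some("r", A)), "t")
        o.add_axiom(SubClassOf(A, Some("s", A)), "t")
        r = Reasoner(o, node_limit=2)
        assert r.check(A) is Verdict.UNDECIDED
        with pytest.raises(Undecided):
            r.is_satisfiable(A)

    def test_spore_class_is_unsatisfiable(self, bundles, reasoner_for):
        r = reasoner_for(bundles["spore"])
        assert not r.is_satisfiable(Named("CL:Spore"))


class TestSubsumption:
    def test_top_subsumes_everything(self):
        r = Reasoner(_empty())
        assert r.subsumes(Top, A)
        assert r.subsumes(Top, Some("r", B))

    def test_asserted_chain(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, B), "t")
        o.add_axiom(SubClassOf(B, C), "t")
        assert Reasoner(o).subsumes(C, A)
        assert not Reasoner(o).subsumes(A, C)

    def test_immune_system_process_is_a_system_process(self, bundles, reasoner_for):
        r = reasoner_for(bundles["leukocyte_activation"])
        assert r.subsumes(Named("GO:SystemProcess"), Named("GO:ImmuneSystemProcess"))

    @pytest.mark.parametrize("seed", range(30))
    def test_random_subsumption_agrees_with_model_search(self, seed):
        o, probe = random_alc_ontology(seed)
        r = Reasoner(o)
        names = sorted(o.signature)
        for a, b in itertools.islice(itertools.combinations(names, 2), 4):
            got = r.subsumes(Named(a), Named(b))
            want = not is_satisfiable_bruteforce(
                o, And.of(Named(b), Not(Named(a))), max_size=4
            )
            assert got == want


class TestUnsatisfiableClasses:
    def test_upper_ontology_alone_is_clean(self):
        from oboreason.convert import build_upper_ontology

        assert Reasoner(build_upper_ontology()).unsatisfiable_classes() == set()

    def test_spore_fixture_closure(self, bundles, reasoner_for):
        r = reasoner_for(bundles["spore"])
        assert r.unsatisfiable_classes() == bundles["spore"].expected["unsatisfiable"]

    def test_monotone_under_axiom_addition(self):
        for seed in range(20):
            o, _ = random_alc_ontology(seed, n_axioms=5)
            base, und = Reasoner(o).unsatisfiable_report()
            assert not und
            o2, _ = random_alc_ontology(seed + 1000, n_axioms=2)
            bigger = o.copy()
            for ax in o2.axioms:
                bigger.add_axiom(ax, "extra")  # same A*/r* signature space
            more, und2 = Reasoner(bigger).unsatisfiable_report()
            assert not und2
            assert base <= more

    def test_existential_dependency_propagates(self):
        o = _empty()
        o.add_axiom(SubClassOf(Named("D"), Bottom), "t")
        o.add_axiom(SubClassOf(C, Some("r", Named("D"))), "t")
        o.add_axiom(SubClassOf(B, Some("s", C)), "t")
        unsat = Reasoner(o).unsatisfiable_classes()
        assert {"D", "C", "B"} <= unsat


class TestClassification:
    def test_asserted_chain_direct_supers(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, B), "t")
        o.add_axiom(SubClassOf(B, C), "t")
        idx = Reasoner(o).classify()
        assert idx.direct_supers["A"] == {"B"}
        assert idx.direct_supers["B"] == {"C"}

    def test_equivalent_classes_share_a_group(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, B), "t")
        o.add_axiom(SubClassOf(B, A), "t")
        idx = Reasoner(o).classify()
        assert idx.equivalents["A"] == idx.equivalents["B"] == frozenset({"A", "B"})

    def test_unsatisfiable_classes_reported_separately(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, Bottom), "t")
        idx = Reasoner(o).classify()
        assert idx.unsatisfiable == {"A"}
        assert "A" not in idx.direct_supers

    @pytest.mark.parametrize("name", ["spore", "leukocyte_activation",
                                      "vasculature_query"])
    def test_index_transitive_closure_equals_pairwise_subsumes(
        self, bundles, reasoner_for, name
    ):
        r = reasoner_for(bundles[name])
        idx = r.classify()
        sat = sorted(idx.direct_supers)
        for a in sat:
            anc = idx.ancestors(a)
            for b in sat:
                if a == b or b in idx.equivalents[a]:
                    continue
                assert (b in anc) == r.subsumes(Named(b), Named(a)), (a, b)


class TestQueries:
    def test_query_top_returns_all_satisfiable_classes(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, B), "t")
        o.add_axiom(SubClassOf(C, Bottom), "t")
        got = Reasoner(o).query_subclasses(Top)
        assert got == {"A", "B"}

    def test_include_unsatisfiable_flag(self):
        o = _empty()
        o.add_axiom(SubClassOf(C, Bottom), "t")
        got = Reasoner(o).query_subclasses(Top, include_unsatisfiable=True)
        assert "C" in got

    def test_vasculature_query_answers(self, bundles, reasoner_for):
        from oboreason.fixtures import VASCULATURE_QUERY
        from oboreason.manchester import parse_expression

        b = bundles["vasculature_query"]
        r = reasoner_for(b)
        got = r.query_subclasses(parse_expression(VASCULATURE_QUERY))
        assert got == b.expected["queries"][VASCULATURE_QUERY]


class TestJustification:
    def _spore_reasoner(self, bundles, reasoner_for):
        return reasoner_for(bundles["spore"])

    def test_single_axiom_justification(self):
        o = _empty()
        o.add_axiom(SubClassOf(A, Bottom), "t")
        assert Reasoner(o).justify("A") == [SubClassOf(A, Bottom)]

    def test_satisfiable_input_is_an_error(self):
        with pytest.raises(ValueError):
            Reasoner(_empty()).justify("A")

    def test_spore_justification_is_the_three_core_axioms(
        self, bundles, reasoner_for
    ):
        r = self._spore_reasoner(bundles, reasoner_for)
        just = r.justify("CL:Spore")
        kinds = {type(ax).__name__ for ax in just}
        assert len(just) == 3
        assert kinds == {"SubClassOf", "EquivalentClasses", "DisjointClasses"}

    def test_justification_is_subset_minimal(self, bundles, reasoner_for):
        r = self._spore_reasoner(bundles, reasoner_for)
        just = r.justify("CL:Spore")
        # removing any single member restores satisfiability
        for i in range(len(just)):
            trimmed = just[:i] + just[i + 1:]
            assert r._subset_satisfiable(trimmed, "CL:Spore")

    def test_exhaustive_search_confirms_minimum_size(self, bundles, reasoner_for):
        r = self._spore_reasoner(bundles, reasoner_for)
        axioms = list(r.ontology.axioms)
        # no subset smaller than 3 keeps Spore unsatisfiable
        for k in (1, 2):
            for subset in itertools.combinations(axioms, k):
                assert r._subset_satisfiable(list(subset), "CL:Spore")


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(60))
    def test_tableau_matches_bounded_model_search(self, seed):
        o, probe = random_alc_ontology(seed)
        r = Reasoner(o)
        for e in [Named(c) for c in sorted(o.signature)] + [probe]:
            assert r.is_satisfiable(e) == is_satisfiable_bruteforce(o, e, 4), e

    @given(exprs())
    def test_nnf_preserves_satisfiability(self, e):
        from oboreason.dl import nnf

        r = Reasoner(_empty())
        assert r.is_satisfiable(e) == r.is_satisfiable(nnf(e))
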