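"""Conversion: upper ontology, templates, expansion, roots, synonyms,
quality constraints and config round-trips."""

import pytest

from oboreason.convert import (
    ConfigError,
    ConversionConfig,
    MATERIAL_OBJECT,
    PROCESS,
    QUALITY,
    FUNCTION,
    RelationTemplate,
    TemplateRegistry,
    add_quality_constraints,
    assign_upper_roots,
    build_upper_ontology,
    builtin_templates,
    canonical_relation,
    convert,
    dump_config,
    expand_template,
    load_config,
    template,
    DEFAULT_SYNONYMS,
)
from oboreason.dl import (
    And,
    Bottom,
    DisjointClasses,
    EquivalentClasses,
    Named,
    Only,
    Some,
    SubClassOf,
    Top,
    normalize_axioms,
)
from oboreason.obo import parse_obo
from oboreason.reasoner import Reasoner


class TestUpperOntology:
    def test_four_roots_pairwise_disjoint(self):
        o = build_upper_ontology()
        dis = [ax for ax in o.axioms if isinstance(ax, DisjointClasses)]
        assert len(dis) == 1 and len(dis[0].members) == 4
        # normalization yields the 6 pairwise bottom-inclusions
        bottoms = [
            ax for ax in normalize_axioms(o).axioms
            if isinstance(ax, SubClassOf) and ax.sup == Bottom
        ]
        assert len(bottoms) == 6

    def test_inheres_in_is_functional_with_unrestricted_range(self):
        o = build_upper_ontology()
        decl = o.roles["inheres_in"]
        assert decl.functional
        assert decl.range is None  # range Thing => no axiom emitted
        assert decl.domain == Named(QUALITY)

    def test_part_of_axioms(self):
        o = build_upper_ontology()
        po = o.roles["part_of"]
        assert po.transitive and po.reflexive and po.inverse == "has_part"
        assert o.roles["proper_part_of"].super_roles == {"part_of"}

    def test_participation_subroles(self):
        o = build_upper_ontology()
        for r in ("has_input", "has_output", "has_central_participant"):
            assert "has_participant" in o.roles[r].super_roles

    def test_table_of_relations_domains(self):
        o = build_upper_ontology()
        assert o.roles["function_of"].domain == Named(FUNCTION)
        assert o.roles["function_of"].inverse == "has_function"
        assert o.roles["has_participant"].domain == Named(PROCESS)
        assert o.roles["has_participant"].range == Named(MATERIAL_OBJECT)
        assert o.roles["realized_by"].domain == Named(FUNCTION)
        assert o.roles["results_in"].range == Named(PROCESS)


class TestTemplates:
    def test_part_of_expansion(self):
        t = builtin_templates()["part_of"]
        assert expand_template(t, Named("Cell")) == Some("part_of", Named("Cell"))

    def test_inheres_in_part_of_expansion(self):
        t = builtin_templates()["inheres_in_part_of"]
        assert expand_template(t, Named("Liver")) == Some(
            "inheres_in", Some("part_of", Named("Liver"))
        )

    def test_capable_of_uses_only_restriction(self):
        t = builtin_templates()["capable_of"]
        assert expand_template(t, Named("P")) == Some(
            "has_function", Only("realized_by", Named("P"))
        )

    def test_template_requires_exactly_one_placeholder(self):
        with pytest.raises(ValueError):
            template("bad", "part_of some Cell")
        with pytest.raises(ValueError):
            template("bad", "part_of some ?Y and has_part some ?Y")

    def test_registry_default_rule_is_total(self):
        reg = TemplateRegistry()
        t = reg.lookup("never_seen_before")
        assert expand_template(t, Named("X")) == Some("never_seen_before", Named("X"))

    def test_results_in_pattern_gets_process_domain(self):
        reg = TemplateRegistry()
        assert reg.fresh_role_domain("results_in_release_of") == PROCESS
        assert reg.fresh_role_domain("part_of_ish") is None


class TestConvert:
    def _convert(self, text, **cfg_kw):
        return convert([parse_obo(text)], ConversionConfig(**cfg_kw))

    def test_relationship_becomes_existential_subclass(self):
        o = self._convert("[Term]\nid: GO:Nucleus\nrelationship: part_of GO:Cell\n")
        assert SubClassOf(
            Named("GO:Nucleus"), Some("part_of", Named("GO:Cell"))
        ) in o.axioms

    def test_intersection_becomes_equivalence(self):
        o = self._convert(
            "[Term]\nid: CL:Spore\nintersection_of: CL:Fungal\n"
            "intersection_of: CL:Prok\n"
        )
        assert EquivalentClasses(
            Named("CL:Spore"), And.of(Named("CL:Fungal"), Named("CL:Prok"))
        ) in o.axioms

    def test_bare_term_contributes_no_axioms(self):
        o = self._convert("[Term]\nid: X:1\nname: lonely\n")
        upper = convert([], ConversionConfig())
        assert len(o.axioms) == len(upper.axioms)
        assert "X:1" in o.signature

    def test_obsolete_terms_are_skipped(self):
        o = self._convert(
            "[Term]\nid: X:1\nis_a: X:2\nis_obsolete: true\n\n[Term]\nid: X:2\n"
        )
        assert not any(
            isinstance(ax, SubClassOf) and ax.sub == Named("X:1")
            for ax in o.axioms
        )

    def test_strip_isa_removes_only_asserted_isa(self):
        text = (
            "[Term]\nid: X:1\nis_a: X:2\nintersection_of: X:2\n"
            "intersection_of: part_of X:3\n\n[Term]\nid: X:2\n\n[Term]\nid: X:3\n"
        )
        o = self._convert(text, strip_asserted_isa=True)
        assert not any(
            o.provenance[ax].endswith(":is_a") for ax in o.axioms
        )
        assert any(isinstance(ax, EquivalentClasses) for ax in o.axioms)

    def test_synonym_variants_unify_to_one_role(self):
        doc_a = parse_obo("[Term]\nid: X:1\nrelationship: has_part X:2\n\n[Term]\nid: X:2\n")
        doc_b = parse_obo("[Term]\nid: Y:1\nrelationship: has-part Y:2\n\n[Term]\nid: Y:2\n")
        o = convert([doc_a, doc_b], ConversionConfig())
        subs = [ax.sup for ax in o.axioms if isinstance(ax, SubClassOf)
                and isinstance(ax.sup, Some)]
        assert {s.role for s in subs} == {"has_part"}

    def test_canonical_relation_normalizes_spaces_and_hyphens(self):
        assert canonical_relation("has part", DEFAULT_SYNONYMS) == "has_part"
        assert canonical_relation("inheres-in", DEFAULT_SYNONYMS) == "inheres_in"
        assert canonical_relation("my-odd-rel", {}) == "my_odd_rel"

    def test_dangling_filler_reported_but_axiom_emitted(self):
        o = self._convert("[Term]\nid: X:1\nrelationship: part_of X:GONE\n")
        assert any("X:GONE" in d for d in o.dangling)
        assert SubClassOf(Named("X:1"), Some("part_of", Named("X:GONE"))) in o.axioms

    def test_typedef_metadata_merged_into_role_box(self):
        text = (
            "[Term]\nid: X:1\nrelationship: regulates X:1\n\n"
            "[Typedef]\nid: regulates\nis_transitive: true\ndomain: X:1\n"
        )
        o = self._convert(text)
        assert o.roles["regulates"].transitive
        assert o.roles["regulates"].domain == Named("X:1")

    def test_conversion_is_deterministic(self):
        b = parse_obo(
            "[Term]\nid: X:1\nrelationship: part_of X:2\n\n[Term]\nid: X:2\n"
        )
        o1 = convert([b], ConversionConfig())
        o2 = convert([b.copy()], ConversionConfig())
        assert o1.axioms == o2.axioms


class TestRootAssignment:
    def test_prefix_maps_to_upper_class(self):
        o = self._converted("[Term]\nid: PATO:0000001\n",
                            root_map={"PATO": QUALITY})
        assert SubClassOf(Named("PATO:0000001"), Named(QUALITY)) in o.axioms

    def _converted(self, text, **kw):
        return convert([parse_obo(text)], ConversionConfig(**kw))

    @pytest.mark.parametrize(
        "mode,target", [("function", FUNCTION), ("process", PROCESS)]
    )
    def test_molecular_function_routed_by_mf_mode(self, mode, target):
        text = "[Term]\nid: GO:1\nnamespace: molecular_function\n"
        o = self._converted(text, mf_mode=mode)
        assert SubClassOf(Named("GO:1"), Named(target)) in o.axioms

    def test_unmatched_prefix_unchanged(self):
        o = self._converted("[Term]\nid: ZZ:1\n", root_map={"PATO": QUALITY})
        assert not any(
            isinstance(ax, SubClassOf) and ax.sub == Named("ZZ:1")
            for ax in o.axioms
        )

    def test_assign_upper_roots_on_existing_ontology(self):
        o = build_upper_ontology()
        o.declare_class("PATO:1")
        o2 = assign_upper_roots(o, {"PATO": QUALITY})
        assert SubClassOf(Named("PATO:1"), Named(QUALITY)) in o2.axioms

    def test_assign_upper_roots_rejects_bad_target(self):
        with pytest.raises(ConfigError):
            assign_upper_roots(build_upper_ontology(), {"X": "NotAThing"})

    def test_bad_root_map_rejected_at_config_time(self):
        with pytest.raises(ConfigError):
            ConversionConfig(root_map={"X": "Banana"})


class TestQualityConstraints:
    def test_exactly_two_axioms_added(self):
        o = build_upper_ontology()
        o.declare_class("PQ")
        o.declare_class("PhQ")
        n0 = len(o.axioms)
        add_quality_constraints(o, "PQ", "PhQ")
        assert len(o.axioms) == n0 + 2
        assert SubClassOf(Named("PQ"), Only("inheres_in", Named(PROCESS))) in o.axioms

    def test_idempotent(self):
        o = build_upper_ontology()
        add_quality_constraints(o, "PQ", "PhQ")
        n = len(o.axioms)
        add_quality_constraints(o, "PQ", "PhQ")
        assert len(o.axioms) == n

    def test_missing_root_is_an_error(self):
        with pytest.raises(ConfigError):
            add_quality_constraints(build_upper_ontology(), None, "PhQ")


class TestConfigIO:
    def test_round_trip(self):
        cfg = ConversionConfig(
            root_map={"PATO": QUALITY, "MA": MATERIAL_OBJECT},
            mf_mode="process",
            strip_asserted_isa=True,
            add_quality_constraints=True,
            process_quality_root="PATO:PQ",
            physical_quality_root="PATO:PhQ",
        )
        cfg2 = load_config(dump_config(cfg))
        assert cfg2.root_map == cfg.root_map
        assert cfg2.mf_mode == "process"
        assert cfg2.strip_asserted_isa and cfg2.add_quality_constraints
        assert cfg2.process_quality_root == "PATO:PQ"

    def test_custom_template_from_yaml(self):
        cfg = load_config(
            'templates:\n  towards: "inheres_in some (towards some ?Y)"\n'
        )
        t = cfg.registry.lookup("towards")
        assert expand_template(t, Named("X")) == Some(
            "inheres_in", Some("towards", Named("X"))
        )

    def test_builtin_disambiguation_selected_by_name(self):
        cfg = load_config("disambiguate: [has_input]\n")
        assert "has_input" in cfg.disambiguation

    def test_unknown_disambiguation_rejected(self):
        with pytest.raises(ConfigError):
            load_config("disambiguate: [made_up_relation]\n")

    def test_invalid_mf_mode_rejected(self):
        with pytest.raises(ConfigError):
            ConversionConfig(mf_mode="banana")
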