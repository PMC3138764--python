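"""OBO flatfile parsing, writing and census statistics."""

import re

import pytest

from oboreason.fixtures import PlantSpec, generate_planted, worked_example
from oboreason.obo import (
    OboParseError,
    count_defined_terms,
    count_relation_usage,
    dangling_references,
    documents_equal,
    parse_obo,
    write_obo,
)

SAMPLE = """format-version: 1.2
ontology: test

[Term]
id: GO:0000001
name: thing one
namespace: biological_process
is_a: GO:0000002 ! parent comment
relationship: part_of GO:0000003 {source="x"}
intersection_of: CL:0000521
intersection_of: part_of GO:0005634

[Term]
id: GO:0000002
name: obsolete thing
is_obsolete: true

[Term]
id: GO:0000003
xref: EXT:1

[Typedef]
id: part_of
name: part of
is_transitive: true
inverse_of: has_part
"""


class TestParsing:
    def test_term_stanza_fields(self):
        doc = parse_obo(SAMPLE)
        t = doc.terms[0]
        assert t.id == "GO:0000001"
        assert t.name == "thing one"
        assert t.namespace == "biological_process"
        assert t.is_a == ["GO:0000002"]
        assert t.relationship == [("part_of", "GO:0000003")]

    def test_intersection_of_with_and_without_relation(self):
        t = parse_obo(SAMPLE).terms[0]
        assert t.intersection_of == [
            (None, "CL:0000521"),
            ("part_of", "GO:0005634"),
        ]

    def test_trailing_comment_stripped_qualifier_kept(self):
        t = parse_obo(SAMPLE).terms[0]
        assert t.qualifiers[("relationship", 0)] == '{source="x"}'

    def test_obsolete_flag(self):
        assert parse_obo(SAMPLE).terms[1].is_obsolete

    def test_unknown_tags_preserved(self):
        t = parse_obo(SAMPLE).terms[2]
        assert [(x.tag, x.value) for x in t.extra] == [("xref", "EXT:1")]

    def test_typedef_metadata(self):
        td = parse_obo(SAMPLE).typedefs[0]
        assert td.is_transitive and td.inverse_of == "has_part"

    def test_line_numbers_recorded(self):
        doc = parse_obo(SAMPLE)
        assert doc.terms[0].line_no == 5

    @pytest.mark.parametrize(
        "text",
        [
            "[Term\nid: X:1\n",
            "[Term]\nid: X:1\nrelationship: only_one_token\n",
            "[Term]\nid: X:1\nmalformed line without colon\n",
            "[Term]\nid: X:1\n\n[Term]\nid: X:1\n",
        ],
    )
    def test_malformed_input_raises_with_line_number(self, text):
        with pytest.raises(OboParseError) as e:
            parse_obo(text)
        assert re.match(r"line \d+:", str(e.value))

    def test_single_intersection_entry_warns(self):
        doc = parse_obo("[Term]\nid: X:1\nintersection_of: X:2\n")
        assert any("single intersection_of" in w for w in doc.warnings)


class TestRoundTrip:
    def test_sample_round_trips(self):
        doc = parse_obo(SAMPLE)
        assert documents_equal(parse_obo(write_obo(doc)), doc)

    @pytest.mark.parametrize("name", ["spore", "liver_inflammation",
                                      "hcp_disambiguation", "vasculature_query"])
    def test_worked_fixtures_round_trip(self, name):
        doc = worked_example(name).document
        assert documents_equal(parse_obo(write_obo(doc)), doc)

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_documents_round_trip(self, seed):
        spec = PlantSpec(seed=seed, n_classes=16,
                         plants={"disjoint_intersection": 1})
        doc = generate_planted(spec).document
        assert documents_equal(parse_obo(write_obo(doc)), doc)

    def test_empty_document_is_header_only(self):
        doc = parse_obo("format-version: 1.2\n")
        assert write_obo(doc) == "format-version: 1.2\n"


def _naive_counts(text):
    """Independent line-scan oracle for the census."""
    rel, defn = {}, {}
    for line in text.splitlines():
        line = line.split("!")[0].strip()
        m = re.match(r"relationship:\s+(\S+)\s+\S+", line)
        if m:
            rel[m.group(1)] = rel.get(m.group(1), 0) + 1
        m = re.match(r"intersection_of:\s+(\S+)\s+(\S+)", line)
        if m:
            defn[m.group(1)] = defn.get(m.group(1), 0) + 1
    return rel, defn


class TestCensus:
    def test_relation_usage_counts(self):
        text = (
            "[Term]\nid: X:1\nrelationship: part_of X:2\n"
            "relationship: part_of X:3\nrelationship: part_of X:4\n\n"
            "[Term]\nid: X:5\nintersection_of: X:2\n"
            "intersection_of: part_of X:3\n"
        )
        table = count_relation_usage([parse_obo(text)])
        row = table[table.relation == "part_of"].iloc[0]
        assert (row.n_relationship, row.n_definition) == (3, 1)

    def test_no_relations_empty_table(self):
        table = count_relation_usage([parse_obo("[Term]\nid: X:1\n")])
        assert len(table) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_text_scan_oracle(self, seed):
        doc = generate_planted(
            PlantSpec(seed=seed, n_classes=20,
                      plants={"domain_violation": 1, "homonymy_merge": 1})
        ).document
        text = write_obo(doc)
        rel, defn = _naive_counts(text)
        table = count_relation_usage([doc])
        got_rel = dict(zip(table.relation, table.n_relationship))
        got_def = dict(zip(table.relation, table.n_definition))
        assert {k: v for k, v in got_rel.items() if v} == rel
        assert {k: v for k, v in got_def.items() if v} == defn

    def test_counts_invariant_under_stanza_reordering(self):
        doc = worked_example("hcp_disambiguation").document
        shuffled = doc.copy()
        shuffled.terms = list(reversed(shuffled.terms))
        a = count_relation_usage([doc])
        b = count_relation_usage([shuffled])
        assert a.equals(b)

    def test_defined_terms_counts_cross_products_only(self):
        text = (
            "[Term]\nid: X:1\nintersection_of: X:2\nintersection_of: X:3\n\n"
            "[Term]\nid: X:2\n\n[Term]\nid: X:3\n\n"
            "[Term]\nid: X:4\nintersection_of: X:2\nintersection_of: X:3\n"
        )
        assert count_defined_terms(parse_obo(text)) == 2

    def test_obsolete_definitions_not_counted(self):
        text = (
            "[Term]\nid: X:1\nintersection_of: X:2\nintersection_of: X:3\n"
            "is_obsolete: true\n"
        )
        assert count_defined_terms(parse_obo(text)) == 0

    @pytest.mark.parametrize("seed,k", [(1, 2), (2, 4)])
    def test_planted_definition_count_matches_generator(self, seed, k):
        doc = generate_planted(
            PlantSpec(seed=seed, n_classes=16,
                      plants={"homonymy_merge": k})
        ).document
        # homonymy plants are the only cross-product definitions the
        # generator makes besides ambiguous/dependent intersections
        assert count_defined_terms(doc) >= k

    def test_defined_terms_bounded_by_term_count(self):
        doc = worked_example("spore").document
        assert count_defined_terms(doc) <= len(doc.terms)


def test_dangling_references_reported():
    doc = parse_obo("[Term]\nid: X:1\nis_a: X:MISSING\n")
    missing = dangling_references([doc])
    assert len(missing) == 1 and missing[0].startswith("X:MISSING")
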