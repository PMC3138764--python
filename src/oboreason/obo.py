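"""OBO 1.2 Flatfile reading, writing and census statistics.

The parser keeps a faithful in-memory image of the file: term and typedef
frames with their tag lines, line numbers for provenance, unknown tags
preserved verbatim, trailing ``{...}`` qualifiers retained (and ignored by
conversion).  ``write_obo(parse_obo(text))`` reparses to a structurally
equal document.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd


class OboParseError(ValueError):
    def __init__(self, message: str, line_no: int):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


@dataclass
class TagLine:
    """One raw tag line: ``tag: value {qualifier} ! comment``."""

    tag: str
    value: str
    qualifier: Optional[str] = None
    line_no: int = 0


@dataclass
class TermFrame:
    id: str = ""
    name: Optional[str] = None
    namespace: Optional[str] = None
    is_a: List[str] = field(default_factory=list)
    relationship: List[Tuple[str, str]] = field(default_factory=list)
    intersection_of: List[Tuple[Optional[str], str]] = field(default_factory=list)
    union_of: List[str] = field(default_factory=list)
    disjoint_from: List[str] = field(default_factory=list)
    is_obsolete: bool = False
    extra: List[TagLine] = field(default_factory=list)
    qualifiers: Dict[Tuple[str, int], str] = field(default_factory=dict)
    line_no: int = 0

    def is_defined(self) -> bool:
        """A *defined term* carries a non-empty cross-product definition."""
        return bool(self.intersection_of) and not self.is_obsolete


@dataclass
class TypedefFrame:
    id: str = ""
    name: Optional[str] = None
    is_a: List[str] = field(default_factory=list)
    is_transitive: bool = False
    is_symmetric: bool = False
    is_reflexive: bool = False
    is_functional: bool = False
    domain: Optional[str] = None
    range: Optional[str] = None
    inverse_of: Optional[str] = None
    extra: List[TagLine] = field(default_factory=list)
    line_no: int = 0


@dataclass
class OboDocument:
    header: List[Tuple[str, str]] = field(default_factory=list)
    terms: List[TermFrame] = field(default_factory=list)
    typedefs: List[TypedefFrame] = field(default_factory=list)
    #: stanza types other than Term/Typedef, kept verbatim
    other_stanzas: List[Tuple[str, List[TagLine]]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    source: str = "<string>"

    def term_ids(self) -> set:
        return {t.id for t in self.terms}

    def typedef_ids(self) -> set:
        return {t.id for t in self.typedefs}

    def term(self, term_id: str) -> TermFrame:
        for t in self.terms:
            if t.id == term_id:
                return t
        raise KeyError(term_id)

    def copy(self) -> "OboDocument":
        import copy as _copy

        return _copy.deepcopy(self)


_QUALIFIER_RE = re.compile(r"\s*(\{[^{}]*\})\s*$")


def _split_line(raw: str, line_no: int) -> Tuple[str, str, Optional[str]]:
    # strip unescaped trailing comment
    out = []
    i = 0
    while i < len(raw):
        c = raw[i]
        if c == "\\" and i + 1 < len(raw):
            out.append(raw[i : i + 2])
            i += 2
            continue
        if c == "!":
            break
        out.append(c)
        i += 1
    line = "".join(out).strip()
    if ":" not in line:
        raise OboParseError(f"malformed tag line: {raw.strip()!r}", line_no)
    tag, value = line.split(":", 1)
    tag = tag.strip()
    value = value.strip()
    qualifier = None
    m = _QUALIFIER_RE.search(value)
    if m:
        qualifier = m.group(1)
        value = value[: m.start()].strip()
    if not tag:
        raise OboParseError(f"empty tag name: {raw.strip()!r}", line_no)
    return tag, value, qualifier


_BOOL = {"true": True, "false": False}

_TERM_SIMPLE = {"id", "name", "namespace", "is_obsolete"}
_TYPEDEF_BOOLS = {
    "is_transitive": "is_transitive",
    "is_symmetric": "is_symmetric",
    "is_reflexive": "is_reflexive",
    "is_functional": "is_functional",
}


def _first_token(value: str) -> str:
    return value.split()[0] if value.split() else ""


def parse_obo(text: Union[str, TextIO], source: str = "<string>") -> OboDocument:
    """Parse OBO 1.2 text into an :class:`OboDocument`.

    Unknown tags are preserved as opaque key/value pairs; every frame and
    tag line records its 1-based line number for provenance.
    """
    if hasattr(text, "read"):
        text = text.read()
    doc = OboDocument(source=source)
    current: Optional[Union[TermFrame, TypedefFrame, list]] = None
    current_kind: Optional[str] = None
    seen_ids: set = set()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            if not stripped.endswith("]") or len(stripped) < 3:
                raise OboParseError(f"malformed stanza header: {stripped!r}", line_no)
            kind = stripped[1:-1]
            if kind == "Term":
                current = TermFrame(line_no=line_no)
                doc.terms.append(current)
            elif kind == "Typedef":
                current = TypedefFrame(line_no=line_no)
                doc.typedefs.append(current)
            else:
                current = []
                doc.other_stanzas.append((kind, current))
            current_kind = kind
            continue
        tag, value, qualifier = _split_line(raw, line_no)
        if current is None:
            doc.header.append((tag, value))
            continue
        if isinstance(current, list):
            current.append(TagLine(tag, value, qualifier, line_no))
            continue
        if isinstance(current, TermFrame):
            _term_tag(doc, current, tag, value, qualifier, line_no, seen_ids)
        else:
            _typedef_tag(doc, current, tag, value, qualifier, line_no, seen_ids)

    for t in doc.terms:
        if not t.id:
            raise OboParseError("[Term] stanza without id", t.line_no)
        if len(t.intersection_of) == 1:
            doc.warnings.append(
                f"{source}:{t.line_no}: term {t.id} has a single intersection_of entry"
            )
    for t in doc.typedefs:
        if not t.id:
            raise OboParseError("[Typedef] stanza without id", t.line_no)
    return doc


def _term_tag(doc, frame: TermFrame, tag, value, qualifier, line_no, seen_ids):
    if tag == "id":
        if value in seen_ids:
            raise OboParseError(f"duplicate id {value!r}", line_no)
        seen_ids.add(value)
        frame.id = value
        frame.line_no = line_no
    elif tag == "name":
        frame.name = value
    elif tag == "namespace":
        frame.namespace = value
    elif tag == "is_obsolete":
        frame.is_obsolete = _BOOL.get(value.lower(), False)
    elif tag == "is_a":
        if qualifier:
            frame.qualifiers[("is_a", len(frame.is_a))] = qualifier
        frame.is_a.append(_first_token(value))
    elif tag == "relationship":
        parts = value.split()
        if len(parts) < 2:
            raise OboParseError(f"relationship needs 'REL ID': {value!r}", line_no)
        if qualifier:
            frame.qualifiers[("relationship", len(frame.relationship))] = qualifier
        frame.relationship.append((parts[0], parts[1]))
    elif tag == "intersection_of":
        parts = value.split()
        if not parts:
            raise OboParseError("empty intersection_of", line_no)
        if qualifier:
            frame.qualifiers[("intersection_of", len(frame.intersection_of))] = qualifier
        if len(parts) == 1:
            frame.intersection_of.append((None, parts[0]))
        else:
            frame.intersection_of.append((parts[0], parts[1]))
    elif tag == "union_of":
        frame.union_of.append(_first_token(value))
    elif tag == "disjoint_from":
        if qualifier:
            frame.qualifiers[("disjoint_from", len(frame.disjoint_from))] = qualifier
        frame.disjoint_from.append(_first_token(value))
    else:
        frame.extra.append(TagLine(tag, value, qualifier, line_no))


def _typedef_tag(doc, frame: TypedefFrame, tag, value, qualifier, line_no, seen_ids):
    if tag == "id":
        frame.id = value
        frame.line_no = line_no
    elif tag == "name":
        frame.name = value
    elif tag == "is_a":
        frame.is_a.append(_first_token(value))
    elif tag in _TYPEDEF_BOOLS:
        setattr(frame, _TYPEDEF_BOOLS[tag], _BOOL.get(value.lower(), False))
    elif tag == "domain":
        frame.domain = _first_token(value)
    elif tag == "range":
        frame.range = _first_token(value)
    elif tag == "inverse_of":
        frame.inverse_of = _first_token(value)
    else:
        frame.extra.append(TagLine(tag, value, qualifier, line_no))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _fmt(tag: str, value: str, qualifier: Optional[str] = None) -> str:
    q = f" {qualifier}" if qualifier else ""
    return f"{tag}: {value}{q}"


def write_obo(doc: OboDocument) -> str:
    """Serialize deterministically.

    Tag order within a ``[Term]`` stanza: id, name, namespace, is_a,
    intersection_of, relationship, disjoint_from, union_of, unknown tags in
    input order, is_obsolete.
    """
    lines: List[str] = []
    for k, v in doc.header:
        lines.append(_fmt(k, v))
    for t in doc.terms:
        lines.append("")
        lines.append("[Term]")
        lines.append(_fmt("id", t.id))
        if t.name is not None:
            lines.append(_fmt("name", t.name))
        if t.namespace is not None:
            lines.append(_fmt("namespace", t.namespace))
        for i, parent in enumerate(t.is_a):
            lines.append(_fmt("is_a", parent, t.qualifiers.get(("is_a", i))))
        for i, (rel, tgt) in enumerate(t.intersection_of):
            value = tgt if rel is None else f"{rel} {tgt}"
            lines.append(_fmt("intersection_of", value, t.qualifiers.get(("intersection_of", i))))
        for i, (rel, tgt) in enumerate(t.relationship):
            lines.append(_fmt("relationship", f"{rel} {tgt}", t.qualifiers.get(("relationship", i))))
        for i, d in enumerate(t.disjoint_from):
            lines.append(_fmt("disjoint_from", d, t.qualifiers.get(("disjoint_from", i))))
        for u in t.union_of:
            lines.append(_fmt("union_of", u))
        for tl in t.extra:
            lines.append(_fmt(tl.tag, tl.value, tl.qualifier))
        if t.is_obsolete:
            lines.append(_fmt("is_obsolete", "true"))
    for t in doc.typedefs:
        lines.append("")
        lines.append("[Typedef]")
        lines.append(_fmt("id", t.id))
        if t.name is not None:
            lines.append(_fmt("name", t.name))
        for parent in t.is_a:
            lines.append(_fmt("is_a", parent))
        if t.domain is not None:
            lines.append(_fmt("domain", t.domain))
        if t.range is not None:
            lines.append(_fmt("range", t.range))
        if t.inverse_of is not None:
            lines.append(_fmt("inverse_of", t.inverse_of))
        for tag, attr in _TYPEDEF_BOOLS.items():
            if getattr(t, attr):
                lines.append(_fmt(tag, "true"))
        for tl in t.extra:
            lines.append(_fmt(tl.tag, tl.value, tl.qualifier))
    for kind, tags in doc.other_stanzas:
        lines.append("")
        lines.append(f"[{kind}]")
        for tl in tags:
            lines.append(_fmt(tl.tag, tl.value, tl.qualifier))
    return "\n".join(lines) + "\n"


def documents_equal(a: OboDocument, b: OboDocument) -> bool:
    """Structural equality ignoring line numbers and source names."""
    return _strip(a) == _strip(b)


def _strip(doc: OboDocument):
    def tagline(tl: TagLine):
        return (tl.tag, tl.value, tl.qualifier)

    def term(t: TermFrame):
        return (
            t.id, t.name, t.namespace, tuple(t.is_a), tuple(t.relationship),
            tuple(t.intersection_of), tuple(t.union_of), tuple(t.disjoint_from),
            t.is_obsolete, tuple(map(tagline, t.extra)),
            tuple(sorted(t.qualifiers.items())),
        )

    def typedef(t: TypedefFrame):
        return (
            t.id, t.name, tuple(t.is_a), t.is_transitive, t.is_symmetric,
            t.is_reflexive, t.is_functional, t.domain, t.range, t.inverse_of,
            tuple(map(tagline, t.extra)),
        )

    return (
        tuple(doc.header),
        tuple(map(term, doc.terms)),
        tuple(map(typedef, doc.typedefs)),
        tuple((k, tuple(map(tagline, v))) for k, v in doc.other_stanzas),
    )


# ---------------------------------------------------------------------------
# Census statistics
# ---------------------------------------------------------------------------


def count_relation_usage(docs: Sequence[OboDocument]) -> pd.DataFrame:
    """Count how often each relation is used.

    One row per relation occurring anywhere, with the number of
    ``relationship:`` lines and the number of relational
    ``intersection_of:`` lines (the formal-definition uses), sorted by
    relationship count descending, then by relation name.
    """
    rel_counts: Dict[str, int] = {}
    def_counts: Dict[str, int] = {}
    for doc in docs:
        for t in doc.terms:
            for rel, _ in t.relationship:
                rel_counts[rel] = rel_counts.get(rel, 0) + 1
                def_counts.setdefault(rel, 0)
            for rel, _ in t.intersection_of:
                if rel is not None:
                    def_counts[rel] = def_counts.get(rel, 0) + 1
                    rel_counts.setdefault(rel, 0)
    rows = [
        {"relation": r, "n_relationship": rel_counts[r], "n_definition": def_counts[r]}
        for r in rel_counts
    ]
    rows.sort(key=lambda row: (-row["n_relationship"], row["relation"]))
    return pd.DataFrame(rows, columns=["relation", "n_relationship", "n_definition"])


def count_defined_terms(doc: OboDocument) -> int:
    """Number of non-obsolete terms with a cross-product definition."""
    return sum(1 for t in doc.terms if t.is_defined())


def dangling_references(docs: Sequence[OboDocument]) -> List[str]:
    """Identifiers referenced by loaded documents but declared in none."""
    declared: set = set()
    for doc in docs:
        declared |= doc.term_ids() | doc.typedef_ids()
    missing: List[str] = []
    seen: set = set()

    def check(ref: str, where: str):
        if ref and ref not in declared and ref not in seen:
            seen.add(ref)
            missing.append(f"{ref} (first referenced at {where})")

    for doc in docs:
        for t in doc.terms:
            where = f"{doc.source}:{t.line_no}:{t.id}"
            for p in t.is_a:
                check(p, where)
            for _, tgt in t.relationship:
                check(tgt, where)
            for _, tgt in t.intersection_of:
                check(tgt, where)
            for d in t.disjoint_from:
                check(d, where)
    return missing
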