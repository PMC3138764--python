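# Methods

This note documents the model, the defaults, the numerical choices and
the limitations of the package — the information a maintainer or reviewer
needs beyond the README's overview.

## The description-logic fragment

Everything the conversion step emits lives in ALC extended with role
hierarchies, inverse roles, transitive roles, functional roles and role
domain/range constraints — the exact closure of the constructs the
method's templates and upper-level relation axioms use.  Nominals,
datatypes and cardinality restrictions beyond functionality are not
supported; OWL 2 RDF/XML is out of scope (a functional-syntax export
exists for external checking).

Class expressions are immutable values.  `And`/`Or` flatten nested
connectives, drop duplicates and neutral elements, and keep arguments in
a canonical order, so structural equality is order-insensitive and
output is deterministic.  Negation normal form pushes `not` onto named
classes; `nnf` is idempotent.

## Conversion semantics

Per non-obsolete term `C` of an OBO document:

| OBO tag | axiom |
|---|---|
| `is_a: D` | `C ⊑ D` (omitted in strip-is-a mode) |
| `relationship: R D` | `C ⊑ expand(template(R), D)` |
| `intersection_of` (≥1 entries) | `C ≡ ⊓ conjuncts` |
| `disjoint_from: D` | `Disjoint(C, D)` |

`intersection_of` yields an *equivalence* (a definition is necessary and
sufficient), while `relationship` yields only a subclass axiom.
Relation names are canonicalized through a synonym map first (hyphen,
space and underscore variants of the same label collapse to one role).
Unregistered relations fall back to a plain existential restriction over
a fresh role; fresh roles matching `results_in_*` receive domain
*Process* — these composites are deliberately *not* expanded, because the specific
process classes needed to define them are missing from the source
vocabularies, yet the Process domain alone suffices to catch their
misuse.  Transport-style composites are likewise left
unexpanded.

Root assignment applies to every class whose identifier prefix matches
the configured map, not only to ontology roots; the redundancy is
harmless under subsumption and keeps the rule simple.  GO terms route by
namespace; the `mf_mode` switch decides whether molecular-function terms
sit under *Function* or *Process*, and both analyses can be run.  In
function mode, molecular-function terms keep their asserted parents;
resulting clashes are reported rather than suppressed.

Strip-is-a mode drops only axioms whose provenance is an `is_a` line;
definition-derived subsumptions and root assignments survive, so
definition-caused contradictions remain detectable.

The optional quality constraints add exactly two axioms:
`ProcessQualityRoot ⊑ ∀inheres_in.Process` and
`PhysicalQualityRoot ⊑ ∀inheres_in.MaterialObject` (idempotently).

When a relation is both registered in the template registry and
described by a typedef stanza, the registry's template wins and
non-conflicting typedef metadata (transitivity, domain, ...) is merged.

### Templates with `only`

`has_function_realized_by` and `capable_of` expand to
`∃has_function.(∀realized_by. ?Y)` as printed in the field's template
tables.  The universal restriction is vacuously satisfied by functions
with no realization; consequently these templates constrain but never
*entail* a realization.  The disambiguation rules for `has_input`/
`has_output` therefore anchor their realized-by reading with an explicit
`Function` conjunct — without it the `only` branch would be vacuously
satisfiable for process classes and no use could ever be resolved to its
intended meaning.

## The tableau reasoner

Standard completion-graph calculus with:

* lazy unfolding plus absorption: axioms with a named class anywhere in
  a left-hand conjunction (`A ⊓ R ⊑ D` ↦ `A ⊑ ¬R ⊔ D`) fire only at
  nodes labelled with that class.  After absorption the internalized
  global-constraint set is empty for all inputs the converter produces,
  which keeps branching local;
* unit propagation over disjunctions (disjuncts whose complement is in
  the label are pruned; a single live disjunct is added
  deterministically), with branching over the smallest live disjunction
  and non-named disjuncts explored first — for absorbed definition
  converses the complement branch usually survives, while asserting the
  defined class cascades through its definition;
* existential successors with role-hierarchy-aware neighbour lookup
  (declared inverses included), universal propagation with the extra
  transitive-subrole step, dedicated domain/range rules on edges
  (semantically equivalent to the textbook GCI compilation
  `∃r.⊤ ⊑ D`, `⊤ ⊑ ∀r.R`, but without its branching overhead);
* functional roles merge surplus neighbours, oldest node wins, labels
  re-trigger expansion;
* reflexive roles are realized as self-loops added at node creation —
  local reflexivity, sufficient for named-class satisfiability tests
  (general reflexivity interacting with blocking across merged nodes is
  a documented limitation);
* pairwise (equality) blocking: a node is blocked by an earlier
  non-root node with the same label whose predecessor has the same
  label and the same connecting edge roles.  Subset blocking would be
  unsound in the presence of inverses and transitivity;
* chronological backtracking, no dependency-directed backjumping —
  adequate at the scale of curated-ontology fixtures.

Resource caps (defaults: 100 000 nodes, 10 000 branches per test) make
non-termination impossible in practice; exceeding a cap yields an
explicit *undecided* verdict that propagates through every API
(`unsatisfiable_report` lists undecided classes separately, the CLI uses
a dedicated exit code).  No performance claims are made beyond the
fixture scale; for full-size ontologies the OWL export path to a
production reasoner exists.

Subsumption is reduced to satisfiability (`sub ⊑ sup` iff
`sub ⊓ ¬sup` is unsatisfiable); classification runs pairwise subsumption
over satisfiable classes and takes the transitive reduction; queries
return the named subclasses of an expression, excluding
Nothing-equivalent classes unless asked.  Justifications use
deletion-based shrinking over the axiom list (deterministic order, one
subset-minimal justification; the role box is held fixed).

## Disambiguation repair

Each rule lists ≥2 alternative readings (first = intended) sharing the
`?Y` placeholder.  Conversion expands a ruled relation to the
disjunction of the readings and records every use site.  Resolution
substitutes one alternative at a time into the using class's own axioms
(other classes keep their disjunctions) and tests that class's
satisfiability: exactly one satisfiable alternative resolves the use;
all satisfiable is reported *ambiguous* (not auto-resolved — an
under-constrained class genuinely supports both readings); none is
*neither*.  Classes with several ambiguous uses are tested over the
cross-product of assignments, capped at 64 combinations (beyond the cap
the uses are flagged undecided).  Rewriting replaces resolved unintended
uses with the rule's composite relation in the source document and adds
the matching typedef, after which strict re-conversion is
contradiction-free for ambiguity-caused clashes only; clashes with other
causes survive by design.

## Synthetic data

The planted-contradiction generator emulates a multi-ontology corpus at
desk scale: four identifier families pre-assigned to the four upper
roots, a random is-a forest per family (default 24 background classes,
depth ≤ 4), and type-safe relation decorations (part_of among material
classes, participation from processes to materials, a single inheres_in
per quality class).  Plants add fresh classes per contradiction
category — disjoint intersections, domain violations, homonymy-style
`results_in_*` misuse, functional-merge clashes, ambiguous
has_central_participant use — plus up to 2 dependent classes each,
chained through existential restrictions so unsatisfiability propagates.
Plants draw hosts and fillers only from the pre-plant background, which
keeps the ground truth exact by construction; the expected set is the
planted classes closed under existential dependency, computed by a
reachability walk over the document, independent of the reasoner.

What the generator does *not* emulate: the scale of real ontology
releases (tens of thousands of classes), annotation noise, multiple
contradiction causes overlapping on one class outside the designed
cases, and relation vocabularies beyond the built-in set.  Passing the
planted-recovery checks therefore demonstrates correctness of the
detection machinery on the modelled contradiction patterns, not
performance or coverage on full GO/MP/HPO releases — whose headline
contradiction counts depend on specific, drifting release files and are
out of scope here.

The random-ontology corpus for the reasoner cross-check stays inside
ALC + role hierarchy + transitive roles with shallow axioms (≤5 classes,
≤2 roles, ≤8 axioms): that fragment has the finite-model property with
small models, so exhaustive model search over domains of ≤4 elements is
an exact, independent oracle.  Inverse/functional combinations are
excluded from the random corpus (they can force larger models) and are
covered by the worked examples instead.

## Problem sizes and determinism

The test suite and the acceptance script run the seven worked examples,
a 200-ontology reasoner cross-check and 100 planted-generator runs
(20 background classes, 1–2 plants per category); the whole acceptance
script completes in well under a minute on one CPU.  All randomness is
seed-derived; identical seeds yield byte-identical generated documents
and identical reports.

## Known limitations

* Reflexivity is local (self-loops), as noted above.
* `union_of` is parsed but not converted (reported as unsupported).
* Only one justification is computed, not all.
* The bounded-model oracle is exact only on fragments with small forced
  models; its "unsatisfiable" verdict means "no model within the bound".
* Obsolete terms are retained in documents but excluded from conversion
  and census counts; dangling references are reported, never silently
  dropped.
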