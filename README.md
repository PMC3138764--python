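# oboreason

Make biomedical ontologies interoperable and reasoning-safe: convert OBO
Flatfile ontologies and their cross-product definitions into
description-logic axioms, align them to a minimal upper-level ontology,
detect contradictory class definitions with a built-in tableau reasoner,
repair ambiguous relation use, and answer expressive cross-ontology
queries.

## The problem

Ontologies such as the Gene Ontology and the mammalian/human phenotype
ontologies increasingly carry *cross-product* definitions — formal class
definitions combining a genus class with relational differentia from
other ontologies (`intersection_of:` tags in OBO files).  These
definitions are only useful for automated reasoning if the semantics of
the relations in them is made explicit.  When it is, a reasoner can find
*unsatisfiable* classes — classes that can have no instances under the
stated axioms, each one signalling an incorrect definition or a
structural error — and can answer queries that span anatomy, process and
phenotype ontologies at once.

## The method

1. **Relation expansion.**  A relation asserted between classes is
   treated as a single-argument template over a class expression.
   `Nucleus relationship: part_of Cell` becomes
   `Nucleus ⊑ ∃part_of.Cell`; a composite relation unfolds into nested
   restrictions, e.g. `inheres_in_part_of` ↦
   `∃inheres_in.(∃part_of. ?Y)` and `capable_of` ↦
   `∃has_function.(∀realized_by. ?Y)`.  Cross-product definitions become
   equivalences: `C ≡ genus ⊓ differentia`.
2. **Upper-level alignment.**  Four pairwise-disjoint upper classes —
   *MaterialObject*, *Process*, *Quality*, *Function* — root every input
   ontology (PATO under Quality, anatomy/cell ontologies under
   MaterialObject, GO by namespace; the molecular-function branch can be
   rooted under Function or Process, both analyses are supported).
   Relations carry domain, range, inverse, transitivity and
   functionality axioms; in particular `inheres_in` is functional (a
   quality inheres in at most one thing) with unrestricted range.
3. **Reasoning.**  A tableau calculus for ALC with role hierarchies,
   inverse, transitive and functional roles decides class
   satisfiability, enumerates unsatisfiable classes, classifies, answers
   subclass queries in a Manchester-like syntax, and shrinks minimal
   justifications.
4. **Repair.**  A relation used in several formally disjoint meanings is
   expanded to the *disjunction* of its readings; the reasoner
   eliminates the contradictory branch per use, and resolved misuses are
   rewritten to new composite relations
   (`inheres_in_has_central_participant`, `realized_by_has_input`, ...).

## Worked example

```sh
$ python examples/01_detect_contradictions.py
unsatisfiable classes (4):
  CL:Spore
  GO:SporeWallAssembly
  GO:SporeWallBiogenesis
  GO:SporulationResultingInFormationOfACellularSpore

minimal justification for CL:Spore:
  DisjointClasses: CL:EukaryoticCell, CL:ProkaryoticCell
  CL:FungalCell SubClassOf: CL:EukaryoticCell
  CL:Spore EquivalentTo: CL:FungalCell and CL:ProkaryoticCell
```

The spore is defined as both a fungal (hence eukaryotic) and a
prokaryotic cell — an impossible intersection — and the three classes
defined in terms of it inherit the contradiction.  The justification is
the minimal axiom set that keeps the class unsatisfiable.

The same pipeline is available as a command-line tool:

```sh
oboreason fixture spore --out work/          # emit OBO + config + expected
oboreason check work/spore.obo --config work/spore.config.yaml --justify
oboreason query ONTOLOGY.obo "Quality and inheres_in some (part_of some MA:Liver)"
oboreason disambiguate ONTOLOGY.obo --relation has_central_participant --out fixed.obo
oboreason stats ONTOLOGY.obo
```

`oboreason check` exits 0 when clean, 1 when contradictions are found,
2 on usage errors and 3 when resource caps left classes undecided.  See
`examples/` for one narrative script per capability (conversion and OWL
export, cross-ontology queries, ambiguity repair, census statistics).

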