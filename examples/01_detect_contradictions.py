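"""Detect contradictory class definitions in an OBO ontology.

Builds the classic spore example: a cell-type ontology defines Spore as the
intersection of FungalCell and ProkaryoticCell, but fungal cells are
eukaryotic cells, which are disjoint from prokaryotic cells.  Converting
the file to description logic and running the tableau reasoner flags the
spore — and every class defined in terms of it — as unsatisfiable, and a
minimal justification names the axioms responsible.
"""

from oboreason import Reasoner, convert, justify, worked_example
from oboreason.manchester import axiom_to_manchester

bundle = worked_example("spore")
ontology = convert([bundle.document], bundle.config)
reasoner = Reasoner(ontology)

unsat, undecided = reasoner.unsatisfiable_report()
print(f"unsatisfiable classes ({len(unsat)}):")
for name in sorted(unsat):
    print(f"  {name}")

print("\nminimal justification for CL:Spore:")
for axiom in reasoner.justify("CL:Spore"):
    print(f"  {axiom_to_manchester(axiom)}")

print(
    "\nEach flagged class can have no instances under the stated axioms; "
    "the justification shows the contradiction needs only the spore's "
    "definition, the fungal-cell parent, and the disjointness axiom."
)
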