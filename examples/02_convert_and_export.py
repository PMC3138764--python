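"""Convert an OBO file into description-logic axioms and export to OWL.

Relations asserted between classes are expanded through single-argument
templates: `relationship: part_of GO:Cell` on the Nucleus term becomes the
axiom `Nucleus SubClassOf: part_of some Cell`, and a cross-product
(`intersection_of`) definition becomes an equivalence.  The result merges
with the four-class upper-level ontology (MaterialObject, Process,
Quality, Function — pairwise disjoint) and can be exported to OWL 2
functional syntax for external reasoners.
"""

from oboreason import ConversionConfig, convert, export_functional, parse_obo
from oboreason.manchester import axiom_to_manchester

OBO = """\
format-version: 1.2

[Term]
id: GO:Nucleus
namespace: cellular_component
relationship: part_of GO:Cell

[Term]
id: GO:Cell
namespace: cellular_component

[Term]
id: MP:SmallNucleus
intersection_of: PATO:DecreasedSize
intersection_of: inheres_in GO:Nucleus

[Term]
id: PATO:DecreasedSize
"""

config = ConversionConfig(root_map={"PATO": "Quality"})
ontology = convert([parse_obo(OBO)], config)

print("axioms derived from the document:")
for ax in ontology.axioms:
    source = ontology.provenance[ax]
    if source not in ("upper-ontology",):
        print(f"  {axiom_to_manchester(ax):70s} [{source}]")

owl = export_functional(ontology)
print(f"\nOWL functional-syntax export: {len(owl.splitlines())} lines, starts:")
print("  " + "\n  ".join(owl.splitlines()[:4]))
print(
    "\nThe nucleus is now a subclass of `part_of some GO:Cell`, and the "
    "phenotype is equivalent to a quality inhering in a nucleus — both "
    "usable in reasoning and cross-ontology queries."
)
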