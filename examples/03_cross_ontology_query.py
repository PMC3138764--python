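"""Answer an expressive query across a phenotype and an anatomy ontology.

Which phenotypes affect the vasculature of abdominal organs?  No single
ontology answers this: the phenotype definitions say `inheres_in_part_of
Liver`, and only the anatomy ontology knows that the liver is an abdominal
organ with blood vessels.  Expanding inheres_in_part_of into the primitive
inheres_in/part_of relations makes the inference possible; turning the
expansion off empties the answer, and adding the missing "kidney blood
vessel is a blood vessel" assertion brings in the kidney phenotype.
"""

from oboreason import Reasoner, convert, worked_example
from oboreason.fixtures import VASCULATURE_QUERY
from oboreason.manchester import parse_expression

bundle = worked_example("vasculature_query")
query = parse_expression(VASCULATURE_QUERY)
print(f"query: {VASCULATURE_QUERY}\n")

for label, b in [
    ("with inheres_in_part_of expansion", bundle),
    ("without expansion", bundle.variants["no_expansion"]),
    ("with the kidney blood-vessel link added", bundle.variants["kidney_link"]),
]:
    reasoner = Reasoner(convert([b.document], b.config))
    answers = sorted(reasoner.query_subclasses(query))
    print(f"{label}:")
    print("  " + ("\n  ".join(answers) if answers else "(no answers)"))

print(
    "\nThe liver phenotypes are retrieved purely through reasoning over "
    "parthood; the kidney phenotype appears once the missing anatomy "
    "assertion is supplied."
)
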