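"""Load the bundled determinants-of-fertility ontology fragment and query it.

Shows the three query primitives: is-a closure (descendants), competency-
question style relation queries, and terminology lookup of consumer
surface forms.
"""

from ontosig import datasets

onto = datasets.fixture_ontology()

print(f"{len(onto.classes)} classes, root: {onto.roots()[0]}")
print("superclasses:", ", ".join(sorted(onto.children("determinants_of_fertility"))))

branch = onto.descendants("individual")
print(f"\n'individual' has {len(branch)} descendant classes, e.g.:",
      ", ".join(sorted(branch)[:5]))

# "What are the personal factors that influence the decision to have a child?"
answer = onto.answer_relation_query("hasIndividual", "determinants_of_fertility")
print(f"\nhasIndividual(determinants_of_fertility) -> {len(answer)} classes")
print("  (the individual branch: every personal factor in the ontology)")

for surface in ("baby bonus", "Childbirth GRANT", "IUD", "zxqv-nonsense"):
    print(f"lookup {surface!r:24} -> {onto.lookup_term(surface)}")
# The first two normalize to synonyms of financial_support_for_childbirth;
# 'iud' is a value-level synonym; unknown strings resolve to None.
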