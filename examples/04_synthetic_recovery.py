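"""Generate a planted synthetic corpus and recover its signal archetypes.

Sixteen keyword concepts are planted with weak / strong / latent / known
presence dynamics over five yearly periods; the full pipeline (synonym
tagging -> DF matrix -> DoD metrics -> issue map) then tries to recover
each keyword's archetype from the generated documents alone.
"""

from ontosig import datasets
from ontosig.pipeline import run_synthetic_recovery
from ontosig.synthetic import default_spec

onto = datasets.fixture_ontology()
spec = default_spec(rng_seed=42)
print(f"{sum(spec.nn_per_period)} documents over {spec.binning.n} periods, "
      f"{len(spec.keywords)} planted keywords")

kim, truth, confusion, accuracy = run_synthetic_recovery(onto, spec)

print("\nconfusion (rows: planted archetype, cols: assigned quadrant):")
print(confusion.to_string())
print(f"\nrecovery accuracy: {accuracy:.3f}")
# 1.0 means every planted archetype landed in its matching quadrant; the
# 'known' archetype corresponds to the not-strong-but-well-known quadrant.
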