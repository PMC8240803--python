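# Methods

## Model and procedure

The pipeline detects future signals in a time-stamped corpus in four
stages.

**Ontology and terminology store.** Classes form an is-a DAG: multiple
parents are allowed, each class must reach exactly one root superclass, and
a class's level is 1 + the maximum parent level (roots are level 0).
Acyclicity is checked by topological sort at load time, and a cycle is
reported with its path. Named relations are (name, domain class, range
class) triples; a relation query returns the range classes of matching
edges unioned with their is-a descendants, which is how competency
questions of the form "which personal factors influence X?" are answered
without a description-logic reasoner. Leaf concepts carry
entity-attribute-value structure: enumerated attributes with non-empty
value sets, or quantities with units. The terminology maps normalized
surface forms (Unicode NFC, case-fold, whitespace collapse; deliberately no
stemming, since terminologies list exact consumer forms) to concepts; a
class's preferred label is an implicit terminology entry. A surface form
mapping to two different concepts of the same kind is a hard load error
rather than first-wins, because a silently ambiguous synonym corrupts every
downstream document-frequency count.

**Coverage evaluation.** Corpus concept labels are mapped through the
terminology; a label is *existing* iff it resolves (class, attribute, or
value synonym), otherwise *new*. The table deduplicates labels within each
contributor group, and deduplicates globally for the total column, so a
concept mentioned by several groups counts once overall — consequently
group totals only add to the grand total when the groups share no labels.
Percentages are rounded half-up to one decimal. A per-label status override
map represents expert review of the automatic mapping.

**Signal statistics.** DoD_ij = (DF_ij / NN_j)(1 − tw(n − j)) with the
conventional time weight tw = 0.05; the configuration requires
tw·(n−1) < 1 so every period weight stays positive, and a period with
NN_j = 0 is a hard error naming the period. The average DoD growth rate is
the mean of consecutive relative changes; pairs with a zero predecessor are
skipped (a relative change from nothing is undefined), and an all-zero
series reports 0.0 with a warning — this keeps the statistic finite on
sparse corpora. The reported average DF rounds half-up to an integer; the
unrounded mean is retained as the map coordinate.

**Issue map.** Coordinates are (average DF, average DoD growth rate);
quadrants split at the joint medians over all mapped keywords (one map, one
split; even counts use the midpoint of the central order statistics).
Tie convention: a keyword exactly on the frequency median counts as
high-frequency (x ≥ median), while one exactly on the growth median counts
as low-growth (strong/weak require y strictly above the median). With an
odd keyword count the growth median *is* one keyword's growth rate, so this
choice is consequential: requiring strictly above-median growth for a
"growing" verdict is the conservative reading, and it is the convention
under which the published fertility issue map is reproduced from its
printed coordinates — there the keyword sitting exactly on the frequency
median (maternity-leave system) is filed under strong and the keyword
sitting exactly on the growth median (conservative values) under
not-strong-but-well-known. A degenerate map where all keywords share one
point therefore labels everything not-strong-but-well-known.

### Known reproduction limits of the published tables

The bundled signal table's yearly columns are raw DF counts: their plain
mean reproduces the printed average DF for all 17 keywords. The printed
average growth-rate column, however, depends on the per-period corpus
totals NN_j, which were never published; it is therefore shipped as an
input (the map's y coordinate), not recomputed, and the growth statistic is
validated by its defining properties instead (fold-oracle equivalence, the
tw = 0 limit, the constant-rate closed form — see below). With the printed
coordinates, one keyword (changing perspectives about marriage, average DF
954 > median 814, growth 0.034 < median 0.036) falls in the
not-strong-but-well-known quadrant although the published classification
lists it as latent — most plausibly because the published map was drawn
from unrounded, NN-normalized coordinates that are not recoverable. The
comparison utility flags it; the package does not patch it. Agreement on
the remaining 16 of 17 keywords is exact.

## Synthetic corpus generator

The generator emulates the statistics the method consumes, not language:
documents are filler tokens (a disjoint `wNNN` vocabulary) plus injected
synonym phrases. Keyword presence is independent Bernoulli per document
with probability base_rate · trend^(j−1) in period j (clipped to [0, 1]);
a present keyword injects one uniformly sampled synonym, exercising
synonym-to-concept grouping in the tagger. It does **not** model
co-occurrence between topics, channel-specific dynamics, bursts, reposts,
or vocabulary drift — passing recovery tests therefore shows the
statistical chain is sound under the planted model, not that real feeds are
this well behaved.

Default study conditions (frozen): 5 yearly periods emulating a
Jan 2011–Jun 2015 window with per-period volumes (2000, 2000, 2000, 2000,
1000) — the final half-year period carries half the volume; 16 keyword
concepts, 4 per archetype, drawn from the 17 concepts of the reference
analysis. Base rates are 0.010–0.025 for the low-frequency archetypes
(weak, latent) and 0.12–0.22 for the high-frequency ones (strong, known);
trends are 1.30–1.50 for the growing archetypes (weak, strong) and
0.72–0.90 for the fading ones (latent, known), paired so that higher base
rates get the weaker trends — this keeps the low- and high-frequency bands
of time-averaged rates separated (≤ 0.045 vs ≥ 0.098) and the median split
well away from both. The archetype/parameter consistency rule (low vs high
base rate at a configurable 0.05 split, growing vs non-growing trend) is
validated before generation. Note that with a constant presence rate the
DoD growth is not zero but the time-weight baseline mean(w_j/w_{j−1} − 1)
≈ 0.057 at tw = 0.05, n = 5; the fading trends (≤ 0.90) stay safely below
the growing ones (≥ 1.30) even after this shift. A 20-seed pilot at these
conditions gave mean recovery accuracy 0.99 (min 0.875), against an
acceptance floor of 0.85.

## Numerical and design choices

- Rounding of reported values (percentages, average DF) is decimal half-up,
  matching how printed tables are rounded by hand; float banker's rounding
  is avoided via `decimal`.
- Top-K keyword selection orders by total DF with lexicographic tie-break
  on concept id; no separate rarity threshold is applied beyond K itself
  (default 17).
- Matrix-entry reanalysis mode: a DF matrix CSV without an NN row can be
  analyzed under an assumed constant NN (the grand DF sum). DoD growth
  rates are invariant to that constant, so growth-based conclusions are
  unchanged; DoD levels under this mode are only defined up to scale.
- The bundled ontology is a fragment (73 classes, the 6 superclasses and
  the branches named in the published hierarchy description, plus the 17
  signal keywords) with a synthetic English terminology standing in for the
  original Korean synonym lists; it exists for tests, examples, and
  simulation, and is not the authors' full 236-class artifact.
- Serialization is plain CSV/JSON (classes, relations, terms; EAV as JSON);
  an OWL exporter is out of scope. Korean morphological analysis is out of
  scope: documents arrive tokenized, and matching is over token n-grams up
  to the longest synonym length.
- Determinism: generation is driven by one `numpy` Generator seeded from
  the spec; identical seeds give byte-identical JSONL corpora and
  byte-identical pipeline CSV outputs.

## Limitations

- Exact-match terminology tagging misses misspellings, inflections, and
  novel slang; a real deployment needs continuous terminology curation.
- The median split forces ~half the keywords to each side of each axis, so
  labels are relative to the analyzed keyword set, not absolute.
- Growth on sparse series is noisy; the zero-predecessor skip rule biases
  growth toward the informative pairs and reports 0 for never-seen
  keywords.
- Problem sizes in tests and the acceptance script (9000-document corpora,
  20 replicates) were chosen as the package's own default study scale;
  larger corpora only tighten the binomial sampling error.
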