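"""Bundled fixtures: a fragment determinants-of-fertility ontology and the
published summary tables of the reference fertility future-signal analysis.

The ontology fragment reconstructs only the classes named in the published
hierarchy description (~75 of the full 236), with a synthetic English
terminology standing in for the original Korean synonym lists; it is a
test/demo artifact, not the authors' ontology.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coverage import EXISTING, NEW, ConceptMention, MappedMention
from .ontology import OntologySet, load_ontology

_DATA = resources.files("ontosig.data")


def fixture_ontology() -> OntologySet:
    """Load the bundled determinants-of-fertility ontology fragment."""
    from contextlib import ExitStack

    with ExitStack() as stack:
        paths = {name: stack.enter_context(resources.as_file(_DATA / name))
                 for name in ("classes.csv", "relations.csv", "eav.json", "terms.csv")}
        return load_ontology(
            class_file=paths["classes.csv"],
            relation_file=paths["relations.csv"],
            eav_file=paths["eav.json"],
            term_file=paths["terms.csv"],
            metadata={"name": "determinants-of-fertility (fragment)", "version": "0.1"},
        )


#: The 17 keyword concepts selected for future-signal analysis.
def signal_table() -> pd.DataFrame:
    """Published per-keyword signal summary: yearly DF counts (2011-2015),
    the printed average DoD growth rate, and the printed average DF.

    The yearly columns are raw document-frequency counts (their plain mean
    reproduces the printed average DF for every row); the per-period corpus
    totals NN_j were never published, so the printed growth-rate column is
    an input here, not a reproducible output."""
    with resources.as_file(_DATA / "table3_signals.csv") as path:
        return pd.read_csv(path, index_col="concept_id")


def reference_labels() -> dict[str, str]:
    """Published four-way signal classification of the 17 keywords."""
    with resources.as_file(_DATA / "table4_labels.csv") as path:
        frame = pd.read_csv(path)
    return dict(zip(frame["concept_id"], frame["signal"]))


#: Published content-coverage counts: unique concepts per contributor group
#: (existing in the ontology vs new), and the globally deduplicated totals.
COVERAGE_COUNTS = {
    "general_public": {"existing": 416, "new": 36},
    "public_servant": {"existing": 93, "new": 2},
    "total": {"existing": 494, "new": 38},
}


def coverage_mention_records() -> list[MappedMention]:
    """Synthetic mapped-mention set reproducing the published coverage
    margins.

    The original 532 unique Korean concepts are not published, so this
    builds placeholder labels with the published per-group counts
    (416 existing + 36 new for the general public, 93 + 2 for public
    servants) and the cross-group overlap those margins imply: 509 - 494 =
    15 existing concepts mentioned by both groups, and no shared new
    concepts (36 + 2 = 38). Statuses are carried directly on the records,
    standing in for terminology lookup against the full ontology."""
    records: list[MappedMention] = []

    def add(count: int, status: str, group: str, prefix: str) -> None:
        for i in range(count):
            mention = ConceptMention(f"{prefix}-{i:04d}", group)
            records.append(MappedMention(mention, status, None))

    shared = 15  # existing concepts mentioned by both groups
    add(shared, EXISTING, "general_public", "shared-existing")
    add(shared, EXISTING, "public_servant", "shared-existing")
    add(416 - shared, EXISTING, "general_public", "gp-existing")
    add(36, NEW, "general_public", "gp-new")
    add(93 - shared, EXISTING, "public_servant", "ps-existing")
    add(2, NEW, "public_servant", "ps-new")
    return records
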