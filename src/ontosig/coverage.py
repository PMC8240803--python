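"""Data-driven content-coverage evaluation of an ontology.

Concept labels harvested from a corpus are mapped against the ontology's
classes and terminology; each unique concept is either *existing* (already
representable) or *new* (a coverage gap). The resulting table — counts and
percentages per contributor group plus a globally deduplicated total — is
the standard data-driven evaluation of how well an ontology covers the
language of its intended users.

Group columns deduplicate concept labels within each group; the Total
column deduplicates globally, so a concept mentioned by several groups is
counted once. The manual expert review step of a real evaluation is
representable through a per-label status override map.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ontology import OntologySet
from .utils import normalize_surface, round_half_up

EXISTING = "existing"
NEW = "new"


@dataclass(frozen=True)
class ConceptMention:
    concept_label: str
    group: str

    def __post_init__(self) -> None:
        if not self.concept_label.strip():
            raise ValueError("concept_label must be non-empty")


@dataclass(frozen=True)
class MappedMention:
    mention: ConceptMention
    status: str  # EXISTING | NEW
    matched_concept_id: str | None


def map_concepts(
    ontology: OntologySet,
    mentions: list[ConceptMention],
    overrides: dict[str, str] | None = None,
) -> list[MappedMention]:
    """Map corpus concept mentions onto the ontology terminology.

    A mention is *existing* iff its normalized label resolves through the
    terminology (as a class, attribute, or value synonym). ``overrides``
    maps normalized labels to forced statuses, standing in for an expert
    review of the automatic mapping.
    """
    overrides = {normalize_surface(k): v for k, v in (overrides or {}).items()}
    mapped = []
    for mention in mentions:
        label = normalize_surface(mention.concept_label)
        concept = ontology.lookup_term(label)
        status = EXISTING if concept is not None else NEW
        if label in overrides:
            status = overrides[label]
            if status not in (EXISTING, NEW):
                raise ValueError(f"override status {status!r} for {label!r}")
        mapped.append(MappedMention(mention, status, concept))
    return mapped


@dataclass
class CoverageTable:
    """Counts and percentages of existing vs new concepts per group."""

    groups: list[str]
    existing: dict[str, int]  # per group, plus "total"
    new: dict[str, int]

    def total(self, column: str) -> int:
        return self.existing[column] + self.new[column]

    def existing_pct(self, column: str) -> float:
        return round_half_up(100.0 * self.existing[column] / self.total(column), 1)

    def new_pct(self, column: str) -> float:
        return round_half_up(100.0 * self.new[column] / self.total(column), 1)

    def to_frame(self) -> pd.DataFrame:
        columns = self.groups + ["total"]
        rows = {
            "existing_count": [self.existing[c] for c in columns],
            "new_count": [self.new[c] for c in columns],
            "total_count": [self.total(c) for c in columns],
            "existing_pct": [self.existing_pct(c) for c in columns],
            "new_pct": [self.new_pct(c) for c in columns],
        }
        return pd.DataFrame(rows, index=columns).T


def coverage_table(mapped: list[MappedMention]) -> CoverageTable:
    """Tabulate unique existing/new concepts per group and overall.

    Labels are deduplicated within each group column and globally for the
    total column. A label must map to one status; contradictory statuses
    (possible only through inconsistent overrides) are rejected.
    """
    if not mapped:
        raise ValueError("coverage_table requires at least one mapped mention")
    status_of: dict[str, str] = {}
    per_group: dict[str, set[str]] = {}
    for record in mapped:
        label = normalize_surface(record.mention.concept_label)
        previous = status_of.get(label)
        if previous is not None and previous != record.status:
            raise ValueError(f"label {label!r} carries contradictory statuses")
        status_of[label] = record.status
        per_group.setdefault(record.mention.group, set()).add(label)

    groups = sorted(per_group)
    existing = {g: sum(1 for lb in labels if status_of[lb] == EXISTING)
                for g, labels in per_group.items()}
    new = {g: sum(1 for lb in labels if status_of[lb] == NEW)
           for g, labels in per_group.items()}
    all_labels = set(status_of)
    existing["total"] = sum(1 for lb in all_labels if status_of[lb] == EXISTING)
    new["total"] = sum(1 for lb in all_labels if status_of[lb] == NEW)
    return CoverageTable(groups=groups, existing=existing, new=new)
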