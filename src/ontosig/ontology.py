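"""Ontology and terminology store for a determinants-of-fertility domain model.

The store holds four layers:

* a class hierarchy (is-a DAG with levelled depth, rooted in a small set of
  superclasses),
* named relations between classes (e.g. ``hasIndividual`` linking the
  domain's top class to the ``individual`` branch),
* an entity-attribute-value (EAV) internal structure for leaf concepts
  (attributes with enumerated value sets or unit-carrying quantities),
* a terminology mapping consumer surface forms ("baby bonus") to concepts.

The query surface is deliberately light: transitive is-a closure and
relation queries combined with that closure, which is what a
terminology-driven social media pipeline needs. Full description-logic
reasoning is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .utils import normalize_surface

CONCEPT_KINDS = ("class", "attribute", "value")


class OntologyError(ValueError):
    """Base class for ontology load/validation failures."""


class StructuralError(OntologyError):
    """Hierarchy violates structural invariants (cycle, multiple roots...)."""


class TermAmbiguityError(OntologyError):
    """One (surface form, kind) pair points at two different concepts."""


class DanglingReferenceError(OntologyError):
    """A relation, term, or EAV entry references a concept that does not exist."""


class UnknownConceptError(KeyError):
    """Lookup of a class id that is not in the ontology."""


class UnknownRelationError(KeyError):
    """Lookup of a relation name that is not in the ontology."""


@dataclass(frozen=True)
class OntologyClass:
    class_id: str
    label: str
    parent_ids: tuple[str, ...]
    level: int


@dataclass(frozen=True)
class RelationDef:
    relation_name: str
    domain_id: str
    range_id: str


@dataclass(frozen=True)
class EavAttribute:
    name: str
    value_type: str  # "enumerated" | "quantity"
    values: tuple[str, ...] = ()
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.value_type not in ("enumerated", "quantity"):
            raise OntologyError(f"unknown value_type {self.value_type!r} for attribute {self.name!r}")
        if self.value_type == "enumerated" and not self.values:
            raise OntologyError(f"enumerated attribute {self.name!r} has an empty value set")
        if self.value_type == "quantity" and not self.unit:
            raise OntologyError(f"quantity attribute {self.name!r} has no unit")


@dataclass(frozen=True)
class EavEntity:
    class_id: str
    attributes: tuple[EavAttribute, ...]


@dataclass(frozen=True)
class TermEntry:
    surface_form: str  # already normalized
    concept_id: str
    concept_kind: str


@dataclass
class OntologySet:
    """A validated ontology + terminology bundle for one domain."""

    classes: dict[str, OntologyClass]
    relations: tuple[RelationDef, ...]
    eav_entities: dict[str, EavEntity]
    terms: tuple[TermEntry, ...]
    metadata: dict = field(default_factory=dict)
    _children: nx.DiGraph = field(init=False, repr=False)
    _term_index: dict[tuple[str, str], str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._children = nx.DiGraph()
        self._children.add_nodes_from(self.classes)
        for cls in self.classes.values():
            for parent in cls.parent_ids:
                if parent not in self.classes:
                    raise DanglingReferenceError(
                        f"class {cls.class_id!r} lists unknown parent {parent!r}")
                self._children.add_edge(parent, cls.class_id)
        self._validate_hierarchy()
        self._validate_relations()
        self._term_index = self._build_term_index()
        self._validate_eav()

    # -- validation -----------------------------------------------------

    def _validate_hierarchy(self) -> None:
        try:
            list(nx.topological_sort(self._children))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(self._children)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise StructuralError(f"is-a hierarchy contains a cycle: {path}") from None
        roots = self.roots()
        if not roots:
            raise StructuralError("hierarchy has no root class")
        for cls in self.classes.values():
            expected = 0 if not cls.parent_ids else 1 + max(
                self.classes[p].level for p in cls.parent_ids)
            if cls.level != expected:
                raise StructuralError(
                    f"class {cls.class_id!r} has level {cls.level}, expected {expected}")
            if cls.parent_ids:
                reachable_roots = {r for r in roots
                                   if r == cls.class_id or nx.has_path(self._children, r, cls.class_id)}
                if len(reachable_roots) != 1:
                    raise StructuralError(
                        f"class {cls.class_id!r} reaches {len(reachable_roots)} root "
                        f"superclasses ({sorted(reachable_roots)}); exactly one required")

    def _validate_relations(self) -> None:
        for rel in self.relations:
            for cid in (rel.domain_id, rel.range_id):
                if cid not in self.classes:
                    raise DanglingReferenceError(
                        f"relation {rel.relation_name!r} references unknown class {cid!r}")

    def _build_term_index(self) -> dict[tuple[str, str], str]:
        index: dict[tuple[str, str], str] = {}
        attribute_ids = {attr.name for ent in self.eav_entities.values() for attr in ent.attributes}
        value_ids = {v for ent in self.eav_entities.values()
                     for attr in ent.attributes for v in attr.values}
        known = {"class": set(self.classes), "attribute": attribute_ids, "value": value_ids}
        entries = list(self.terms)
        # Class labels are implicit terminology entries.
        entries += [TermEntry(normalize_surface(c.label), c.class_id, "class")
                    for c in self.classes.values()]
        for entry in entries:
            if entry.concept_kind not in CONCEPT_KINDS:
                raise OntologyError(f"unknown concept_kind {entry.concept_kind!r}")
            if entry.concept_id not in known[entry.concept_kind]:
                raise DanglingReferenceError(
                    f"term {entry.surface_form!r} references unknown "
                    f"{entry.concept_kind} {entry.concept_id!r}")
            key = (entry.surface_form, entry.concept_kind)
            previous = index.get(key)
            if previous is not None and previous != entry.concept_id:
                raise TermAmbiguityError(
                    f"surface form {entry.surface_form!r} ({entry.concept_kind}) maps to "
                    f"both {previous!r} and {entry.concept_id!r}")
            index[key] = entry.concept_id
        return index

    def _validate_eav(self) -> None:
        for class_id in self.eav_entities:
            if class_id not in self.classes:
                raise DanglingReferenceError(f"EAV entity references unknown class {class_id!r}")

    # -- queries --------------------------------------------------------

    def roots(self) -> list[str]:
        return sorted(c.class_id for c in self.classes.values() if not c.parent_ids)

    def children(self, class_id: str) -> set[str]:
        self._require_class(class_id)
        return set(self._children.successors(class_id))

    def descendants(self, class_id: str) -> set[str]:
        """Transitive closure of is-a children, excluding the class itself."""
        self._require_class(class_id)
        return set(nx.descendants(self._children, class_id))

    def answer_relation_query(self, relation_name: str, target_class_id: str) -> set[str]:
        """Answer a competency-question style query over one named relation.

        Returns every range class of a ``relation_name`` edge whose domain is
        ``target_class_id``, unioned with all is-a descendants of those range
        classes — the combination of a named relation with the is-a closure
        that a description-logic query such as "IsIndividualOf some
        Determinants_of_fertility" resolves to.
        """
        self._require_class(target_class_id)
        matching = [r for r in self.relations if r.relation_name == relation_name]
        if not matching:
            raise UnknownRelationError(relation_name)
        result: set[str] = set()
        for rel in matching:
            if rel.domain_id == target_class_id:
                result.add(rel.range_id)
                result |= self.descendants(rel.range_id)
        return result

    def lookup_term(self, surface_form: str, kind: str | None = None) -> str | None:
        """Resolve a surface form to a concept id, or ``None`` when absent.

        Matching is exact after normalization (NFC, case-fold, whitespace
        collapse). When ``kind`` is not given, class concepts are preferred
        over attributes over values.
        """
        surface = normalize_surface(surface_form)
        if not surface:
            return None
        kinds = (kind,) if kind is not None else CONCEPT_KINDS
        for k in kinds:
            hit = self._term_index.get((surface, k))
            if hit is not None:
                return hit
        return None

    def class_synonyms(self, concept_id: str) -> set[str]:
        """All normalized surface forms naming a class (label + synonyms)."""
        self._require_class(concept_id)
        forms = {surface for (surface, kind), cid in self._term_index.items()
                 if kind == "class" and cid == concept_id}
        return forms

    def _require_class(self, class_id: str) -> None:
        if class_id not in self.classes:
            raise UnknownConceptError(class_id)


# -- loading -------------------------------------------------------------


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise OntologyError(f"{path}: missing columns {missing}")
    return frame


def load_ontology(
    class_file: str | Path,
    relation_file: str | Path | None = None,
    eav_file: str | Path | None = None,
    term_file: str | Path | None = None,
    metadata: Mapping | None = None,
) -> OntologySet:
    """Load and validate an ontology from its CSV/JSON serialization.

    ``classes.csv`` columns: class_id,label,parent_ids (``;``-separated),level
    (level may be blank, in which case it is derived from the parents).
    ``relations.csv``: relation_name,domain_id,range_id.
    ``terms.csv``: surface_form,concept_id,concept_kind.
    ``eav.json``: ``{class_id: [{attribute, value_type, unit?, values?}]}``.
    """
    class_frame = _read_csv(Path(class_file), ["class_id", "label", "parent_ids"])

    classes: dict[str, OntologyClass] = {}
    raw: list[tuple[str, str, tuple[str, ...], str]] = []
    for row in class_frame.itertuples(index=False):
        parents = tuple(p for p in str(getattr(row, "parent_ids", "")).split(";") if p)
        level_txt = str(getattr(row, "level", "")).strip()
        raw.append((row.class_id, row.label, parents, level_txt))
    # Derive levels where blank: longest path from a root, computed iteratively.
    levels: dict[str, int] = {}
    pending = list(raw)
    while pending:
        progressed = False
        still = []
        for cid, label, parents, level_txt in pending:
            if all(p in levels for p in parents):
                levels[cid] = 0 if not parents else 1 + max(levels[p] for p in parents)
                progressed = True
            else:
                still.append((cid, label, parents, level_txt))
        if not progressed:
            # A parent never resolves: either a cycle or a dangling parent;
            # build with stated/zero levels and let validation name the fault.
            for cid, _, parents, level_txt in still:
                levels[cid] = int(level_txt) if level_txt else 0
            break
        pending = still
    for cid, label, parents, level_txt in raw:
        if cid in classes:
            raise OntologyError(f"duplicate class_id {cid!r}")
        level = int(level_txt) if level_txt else levels[cid]
        classes[cid] = OntologyClass(cid, label, parents, level)

    relations: list[RelationDef] = []
    if relation_file is not None:
        rel_frame = _read_csv(Path(relation_file), ["relation_name", "domain_id", "range_id"])
        relations = [RelationDef(r.relation_name, r.domain_id, r.range_id)
                     for r in rel_frame.itertuples(index=False)]

    eav_entities: dict[str, EavEntity] = {}
    if eav_file is not None:
        payload = json.loads(Path(eav_file).read_text(encoding="utf-8"))
        for class_id, attrs in payload.items():
            eav_entities[class_id] = EavEntity(
                class_id,
                tuple(EavAttribute(
                    name=a["attribute"],
                    value_type=a["value_type"],
                    values=tuple(a.get("values", ())),
                    unit=a.get("unit"),
                ) for a in attrs),
            )

    terms: list[TermEntry] = []
    if term_file is not None:
        term_frame = _read_csv(Path(term_file), ["surface_form", "concept_id", "concept_kind"])
        terms = [TermEntry(normalize_surface(r.surface_form), r.concept_id, r.concept_kind)
                 for r in term_frame.itertuples(index=False)]

    return OntologySet(
        classes=classes,
        relations=tuple(relations),
        eav_entities=eav_entities,
        terms=tuple(terms),
        metadata=dict(metadata or {}),
    )
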