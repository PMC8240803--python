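"""Terminology-based corpus tagging and document-frequency matrices.

Documents arrive tokenized (the tokenizer is an input contract — matching
is language-agnostic over the token stream). A keyword concept is *present*
in a document when any of its synonyms, including its preferred label,
occurs as a contiguous token n-gram; presence is coded 0/1 per document, so
repeated occurrences and multiple synonyms of one concept still count once.
Binning presence vectors by calendar period yields the keyword x period
document-frequency matrix DF_ij together with the per-period document
totals NN_j that every downstream signal statistic consumes.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologySet
from .utils import normalize_surface

#: Channel kinds of the emulated social-media feed.
CHANNELS = ("online_news", "message_board", "sns", "blog", "community")

NN_ROW = "__NN__"


class BinningError(ValueError):
    """A document's timestamp falls outside every configured period."""


@dataclass(frozen=True)
class Document:
    """One social-media post: id, channel, date, optional group, tokens."""

    doc_id: str
    channel: str
    timestamp: dt.date
    group: str | None
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Period:
    label: str
    start: dt.date
    end: dt.date  # inclusive

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class PeriodBinning:
    """Disjoint, ordered periods covering the study window."""

    periods: list[Period]

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("at least one period required")
        for before, after in zip(self.periods, self.periods[1:]):
            if before.end >= after.start:
                raise ValueError(
                    f"periods {before.label!r} and {after.label!r} overlap or are unordered")

    @classmethod
    def yearly(cls, start: dt.date, end: dt.date) -> "PeriodBinning":
        """Calendar-year bins over [start, end]; boundary years are clipped,
        so a study window ending mid-year yields a short final period."""
        periods = []
        for year in range(start.year, end.year + 1):
            periods.append(Period(
                label=str(year),
                start=max(start, dt.date(year, 1, 1)),
                end=min(end, dt.date(year, 12, 31)),
            ))
        return cls(periods)

    @property
    def n(self) -> int:
        return len(self.periods)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.periods]

    def assign(self, day: dt.date) -> int:
        for j, period in enumerate(self.periods):
            if day in period:
                return j
        raise BinningError(f"date {day.isoformat()} is outside all configured periods")


@dataclass
class KeywordPeriodMatrix:
    """DF_ij counts for keywords i over periods j, plus NN_j totals."""

    keywords: list[str]  # concept ids
    period_labels: list[str]
    df: np.ndarray  # (K, n) int
    nn: np.ndarray  # (n,) int
    labels: dict[str, str] = field(default_factory=dict)  # concept_id -> display label

    def __post_init__(self) -> None:
        self.df = np.asarray(self.df, dtype=np.int64)
        self.nn = np.asarray(self.nn, dtype=np.int64)
        if self.df.shape != (len(self.keywords), len(self.period_labels)):
            raise ValueError("df shape does not match keywords x periods")
        if self.nn.shape != (len(self.period_labels),):
            raise ValueError("nn length does not match periods")
        if (self.df < 0).any() or (self.df > self.nn[None, :]).any():
            raise ValueError("DF counts must satisfy 0 <= DF_ij <= NN_j")

    @property
    def n(self) -> int:
        return len(self.period_labels)

    def total_df(self) -> np.ndarray:
        return self.df.sum(axis=1)

    def subset(self, keywords: Sequence[str]) -> "KeywordPeriodMatrix":
        index = {k: i for i, k in enumerate(self.keywords)}
        rows = [index[k] for k in keywords]
        return KeywordPeriodMatrix(
            keywords=list(keywords),
            period_labels=list(self.period_labels),
            df=self.df[rows],
            nn=self.nn.copy(),
            labels={k: self.labels.get(k, k) for k in keywords},
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.df, index=self.keywords, columns=self.period_labels)
        frame.loc[NN_ROW] = self.nn
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="keyword")

    @classmethod
    def from_csv(cls, path: str | Path, nn: Sequence[int] | None = None,
                 assume_constant_nn: bool = False) -> "KeywordPeriodMatrix":
        """Read a DF matrix CSV (keywords x periods, optional NN row).

        When the file carries no NN row and none is supplied,
        ``assume_constant_nn`` substitutes one constant total (the grand DF
        sum) for every period. Degree-of-diffusion growth rates are
        invariant to that constant, so this mode supports reanalysis of
        published DF tables whose per-period totals were never released.
        """
        frame = pd.read_csv(path, index_col=0)
        if NN_ROW in frame.index:
            nn_arr = frame.loc[NN_ROW].to_numpy(dtype=np.int64)
            frame = frame.drop(index=NN_ROW)
        elif nn is not None:
            nn_arr = np.asarray(list(nn), dtype=np.int64)
        elif assume_constant_nn:
            nn_arr = np.full(frame.shape[1], int(frame.to_numpy().sum()), dtype=np.int64)
        else:
            raise ValueError(f"{path}: no NN row; pass nn= or assume_constant_nn=True")
        return cls(
            keywords=[str(k) for k in frame.index],
            period_labels=[str(c) for c in frame.columns],
            df=frame.to_numpy(dtype=np.int64),
            nn=nn_arr,
        )


# -- tagging --------------------------------------------------------------


def _synonym_index(ontology: OntologySet,
                   keyword_concepts: Sequence[str]) -> tuple[dict[str, set[int]], int]:
    """Phrase -> keyword-row-index sets, plus the longest phrase length."""
    index: dict[str, set[int]] = {}
    max_len = 1
    for row, concept in enumerate(keyword_concepts):
        for phrase in ontology.class_synonyms(concept):
            index.setdefault(phrase, set()).add(row)
            max_len = max(max_len, len(phrase.split()))
    return index, max_len


def _document_ngrams(tokens: Sequence[str], max_len: int) -> set[str]:
    normalized = [normalize_surface(t) for t in tokens]
    grams: set[str] = set()
    for length in range(1, max_len + 1):
        for i in range(len(normalized) - length + 1):
            grams.add(" ".join(normalized[i:i + length]))
    return grams


def tag_documents(
    ontology: OntologySet,
    docs: Sequence[Document],
    keyword_concepts: Sequence[str],
) -> np.ndarray:
    """Binary presence matrix (documents x keywords).

    presence[d, i] = 1 iff any synonym (or the label) of concept i occurs as
    a contiguous n-gram in document d. Raises ``UnknownConceptError`` for a
    keyword concept absent from the ontology.
    """
    index, max_len = _synonym_index(ontology, keyword_concepts)
    presence = np.zeros((len(docs), len(keyword_concepts)), dtype=np.int8)
    for d, doc in enumerate(docs):
        hits = _document_ngrams(doc.tokens, max_len) & index.keys()
        for phrase in hits:
            for row in index[phrase]:
                presence[d, row] = 1
    return presence


def build_df_matrix(
    ontology: OntologySet,
    docs: Sequence[Document],
    binning: PeriodBinning,
    keyword_concepts: Sequence[str],
) -> KeywordPeriodMatrix:
    """Tag documents and aggregate presence into a DF matrix.

    NN_j counts every document binned into period j regardless of keyword
    content; a document outside all periods raises ``BinningError``.
    """
    bins = np.array([binning.assign(doc.timestamp) for doc in docs], dtype=np.int64)
    presence = tag_documents(ontology, docs, keyword_concepts)
    n = binning.n
    df = np.zeros((len(keyword_concepts), n), dtype=np.int64)
    nn = np.zeros(n, dtype=np.int64)
    for j in range(n):
        mask = bins == j
        nn[j] = int(mask.sum())
        df[:, j] = presence[mask].sum(axis=0)
    labels = {c: ontology.classes[c].label for c in keyword_concepts}
    return KeywordPeriodMatrix(list(keyword_concepts), binning.labels, df, nn, labels)


def select_top_keywords(matrix: KeywordPeriodMatrix, k: int) -> list[str]:
    """The K keywords with the largest total DF across periods.

    Rarely used keywords distort average frequencies and growth rates, so
    signal analysis restricts itself to the most frequent concepts (the
    reference analysis used K=17). Ties break lexicographically by concept
    id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix.keywords):
        raise ValueError(f"k={k} exceeds the {len(matrix.keywords)} candidate keywords")
    totals = matrix.total_df()
    order = sorted(range(len(matrix.keywords)),
                   key=lambda i: (-int(totals[i]), matrix.keywords[i]))
    return [matrix.keywords[i] for i in order[:k]]


# -- corpus serialization --------------------------------------------------


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for doc in docs:
            handle.write(json.dumps({
                "doc_id": doc.doc_id,
                "channel": doc.channel,
                "date": doc.timestamp.isoformat(),
                "group": doc.group,
                "tokens": list(doc.tokens),
            }, ensure_ascii=False) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    docs = []
    with Path(path).open("r", encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            raw = json.loads(line)
            docs.append(Document(
                doc_id=str(raw["doc_id"]),
                channel=str(raw["channel"]),
                timestamp=dt.date.fromisoformat(raw["date"]),
                group=raw.get("group"),
                tokens=tuple(raw["tokens"]),
            ))
    return docs
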