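"""Synthetic social-media corpora with planted signal structure.

Real future-signal corpora are crawled from hundreds of channels and are
rarely redistributable, so the pipeline is exercised on generated corpora
that emulate the statistics the method actually consumes: per-period
document volumes and per-keyword presence probabilities with planted
temporal trends. Each keyword follows one of four archetypes matching the
signal taxonomy:

* ``weak``   — low base presence rate, growing trend (rate multiplier > 1)
* ``strong`` — high base rate, growing trend
* ``latent`` — low base rate, flat or decaying trend
* ``known``  — high base rate, flat or decaying trend (maps to the
  not-strong-but-well-known quadrant)

Presence is independent Bernoulli per keyword per document (the DF/DoD
statistics only consume marginal counts, so no co-occurrence model is
needed). A present keyword is realized by injecting one uniformly sampled
synonym from the ontology terminology into the document's filler tokens,
which also exercises synonym-to-concept grouping in the tagger.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kim import LABELS, NOT_STRONG, KimResult
from .ontology import OntologySet
from .tagging import CHANNELS, Document, Period, PeriodBinning

ARCHETYPES = ("weak", "strong", "latent", "known")

#: Quadrant label each archetype should earn on the issue map.
ARCHETYPE_TO_LABEL = {"weak": "weak", "strong": "strong",
                      "latent": "latent", "known": NOT_STRONG}

#: Base-rate threshold separating "low frequency" from "high frequency"
#: archetypes (configurable).
DEFAULT_RATE_SPLIT = 0.05


class GenerationError(ValueError):
    """The corpus spec cannot be realized against the given ontology."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Planted behaviour of one keyword: period-1 presence probability and
    a multiplicative per-period trend."""

    archetype: str
    base_rate: float
    trend: float

    def validate(self, rate_split: float = DEFAULT_RATE_SPLIT) -> None:
        if self.archetype not in ARCHETYPES:
            raise GenerationError(f"unknown archetype {self.archetype!r}")
        if not 0.0 < self.base_rate < 1.0:
            raise GenerationError(f"base_rate must be in (0,1), got {self.base_rate}")
        if self.trend <= 0:
            raise GenerationError(f"trend must be positive, got {self.trend}")
        growing = self.trend > 1.0
        low = self.base_rate < rate_split
        expected = {"weak": (True, True), "strong": (False, True),
                    "latent": (True, False), "known": (False, False)}
        if (low, growing) != expected[self.archetype]:
            raise GenerationError(
                f"archetype {self.archetype!r} inconsistent with base_rate="
                f"{self.base_rate}, trend={self.trend} (rate split {rate_split})")


@dataclass
class CorpusSpec:
    """Everything needed to generate one corpus reproducibly."""

    nn_per_period: tuple[int, ...]
    binning: PeriodBinning
    keywords: dict[str, ArchetypeSpec]  # concept_id -> archetype
    rng_seed: int
    synonym_sampling: bool = True
    rate_split: float = DEFAULT_RATE_SPLIT
    filler_tokens: int = 8
    filler_vocab: int = 200
    group: str | None = None

    def __post_init__(self) -> None:
        if len(self.nn_per_period) != self.binning.n:
            raise GenerationError("nn_per_period length must match the binning")
        if any(nn < 1 for nn in self.nn_per_period):
            raise GenerationError("every period needs NN_j >= 1")
        for spec in self.keywords.values():
            spec.validate(self.rate_split)

    def planted_rates(self) -> np.ndarray:
        """Presence probability per keyword and period, clipped to [0, 1]."""
        n = self.binning.n
        rates = np.empty((len(self.keywords), n))
        for i, spec in enumerate(self.keywords.values()):
            rates[i] = spec.base_rate * spec.trend ** np.arange(n)
        return np.clip(rates, 0.0, 1.0)


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated corpus."""

    archetypes: dict[str, str]  # concept_id -> archetype
    rates: np.ndarray  # (K, n) planted presence probabilities

    def expected_labels(self) -> dict[str, str]:
        return {k: ARCHETYPE_TO_LABEL[a] for k, a in self.archetypes.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"archetype": self.archetypes}).rename_axis("keyword")


def generate_corpus(ontology: OntologySet,
                    spec: CorpusSpec) -> tuple[list[Document], PlantedTruth]:
    """Generate a corpus with planted per-keyword presence trends.

    In period j (0-based), each keyword i is present in each document
    independently with probability ``base_rate_i * trend_i**j``; when
    present, one synonym (uniform over the concept's terminology, or the
    class label when synonym sampling is off) is appended to the filler
    tokens. Fully reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    keyword_ids = list(spec.keywords)
    pools: list[list[str]] = []
    for concept in keyword_ids:
        if spec.synonym_sampling:
            pool = sorted(ontology.class_synonyms(concept))
        else:
            pool = [ontology.classes[concept].label.casefold()]
        if not pool:
            raise GenerationError(f"keyword concept {concept!r} has no synonyms")
        pools.append(pool)

    rates = spec.planted_rates()
    docs: list[Document] = []
    for j, period in enumerate(spec.binning.periods):
        nn = spec.nn_per_period[j]
        n_days = (period.end - period.start).days + 1
        presence = rng.random((nn, len(keyword_ids))) < rates[:, j][None, :]
        day_offsets = rng.integers(0, n_days, size=nn)
        channel_idx = rng.integers(0, len(CHANNELS), size=nn)
        fillers = rng.integers(0, spec.filler_vocab, size=(nn, spec.filler_tokens))
        synonym_idx = rng.integers(0, 2 ** 30, size=(nn, len(keyword_ids)))
        for d in range(nn):
            tokens = [f"w{v:03d}" for v in fillers[d]]
            for i in np.flatnonzero(presence[d]):
                phrase = pools[i][synonym_idx[d, i] % len(pools[i])]
                tokens.extend(phrase.split())
            docs.append(Document(
                doc_id=f"{period.label}-{d:06d}",
                channel=CHANNELS[channel_idx[d]],
                timestamp=period.start + dt.timedelta(days=int(day_offsets[d])),
                group=spec.group,
                tokens=tuple(tokens),
            ))
    truth = PlantedTruth(
        archetypes={k: spec.keywords[k].archetype for k in keyword_ids},
        rates=rates,
    )
    return docs, truth


def recovery_report(planted: PlantedTruth,
                    kim: KimResult) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (planted archetype x assigned quadrant) and overall
    recovery accuracy. The keyword sets must coincide."""
    if set(planted.archetypes) != set(kim.keywords):
        raise ValueError("planted truth and KIM cover different keyword sets")
    confusion = pd.DataFrame(0, index=list(ARCHETYPES), columns=list(LABELS))
    correct = 0
    for keyword, archetype in planted.archetypes.items():
        assigned = kim.label_of(keyword)
        confusion.loc[archetype, assigned] += 1
        if ARCHETYPE_TO_LABEL[archetype] == assigned:
            correct += 1
    return confusion, correct / len(planted.archetypes)


# -- default study-condition spec -----------------------------------------

#: Frozen default: 16 keyword concepts, 4 per archetype, drawn from the 17
#: concepts selected in the reference fertility analysis. Base rates and
#: trends pair higher base rates with weaker trends so each archetype's
#: average-DF band stays separated.
DEFAULT_ARCHETYPE_ASSIGNMENT: dict[str, ArchetypeSpec] = {
    # weak: rare but spreading
    "violence_and_abuse": ArchetypeSpec("weak", 0.010, 1.50),
    "flexible_working_arrangement": ArchetypeSpec("weak", 0.015, 1.43),
    "financial_support_for_employment_security": ArchetypeSpec("weak", 0.020, 1.36),
    "gender_inequality": ArchetypeSpec("weak", 0.025, 1.30),
    # strong: common and still growing
    "economic_problems": ArchetypeSpec("strong", 0.12, 1.50),
    "population_aging": ArchetypeSpec("strong", 0.15, 1.43),
    "nuclearization_of_the_family": ArchetypeSpec("strong", 0.18, 1.36),
    "child_safety_protection_system": ArchetypeSpec("strong", 0.22, 1.30),
    # latent: rare and fading
    "employment_problems": ArchetypeSpec("latent", 0.010, 0.90),
    "smart_work_center": ArchetypeSpec("latent", 0.015, 0.84),
    "family_friendly_work_environment": ArchetypeSpec("latent", 0.020, 0.78),
    "policy_public_relations": ArchetypeSpec("latent", 0.025, 0.72),
    # known: common but plateauing/declining
    "financial_support_for_childbirth": ArchetypeSpec("known", 0.12, 0.90),
    "infrastructure_for_childcare_support": ArchetypeSpec("known", 0.15, 0.84),
    "conservative_values": ArchetypeSpec("known", 0.18, 0.78),
    "changing_perspectives_about_marriage": ArchetypeSpec("known", 0.22, 0.72),
}

#: Emulates the reference study window: 5 yearly periods, Jan 2011-Jun 2015,
#: last period at half document volume.
DEFAULT_NN = (2000, 2000, 2000, 2000, 1000)
DEFAULT_WINDOW = (dt.date(2011, 1, 1), dt.date(2015, 6, 30))


def default_spec(rng_seed: int = 42, *,
                 nn_per_period: tuple[int, ...] = DEFAULT_NN,
                 keywords: Mapping[str, ArchetypeSpec] | None = None) -> CorpusSpec:
    """The frozen default study conditions for parameter-recovery runs."""
    return CorpusSpec(
        nn_per_period=tuple(nn_per_period),
        binning=PeriodBinning.yearly(*DEFAULT_WINDOW),
        keywords=dict(keywords if keywords is not None else DEFAULT_ARCHETYPE_ASSIGNMENT),
        rng_seed=rng_seed,
    )
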