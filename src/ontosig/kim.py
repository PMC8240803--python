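"""Keyword issue map (KIM) construction and four-way signal classification.

The KIM scatters each keyword at (x, y) = (average DF, average DoD growth
rate) and splits the plane at the joint medians of the two coordinates:

* strong signals            — x >= x_median, y >  y_median (established and growing)
* weak signals              — x <  x_median, y >  y_median (rare but spreading fast)
* latent signals            — x <  x_median, y <= y_median (not yet noticeable)
* not-strong-but-well-known — x >= x_median, y <= y_median (established, plateauing)

Tie convention: a keyword sitting exactly on the x median counts as
high-frequency, while one sitting exactly on the y median counts as
low-growth. With an odd keyword count the y median is itself one keyword's
growth rate, so the y tie rule decides that keyword's fate; demanding
strictly above-median growth for a "growing" call is the conservative
choice, and it is the convention under which the published fertility
issue map is reproduced from its printed coordinates (the keyword sitting
exactly on the growth median is filed under not-strong-but-well-known
there, while the keyword sitting exactly on the frequency median is filed
under strong).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRONG = "strong"
WEAK = "weak"
LATENT = "latent"
NOT_STRONG = "not_strong_but_well_known"
LABELS = (WEAK, STRONG, LATENT, NOT_STRONG)


@dataclass
class KimResult:
    keywords: list[str]
    x: np.ndarray  # average DF (unrounded)
    y: np.ndarray  # average DoD growth rate
    x_median: float
    y_median: float
    labels: list[str]

    def label_of(self, keyword: str) -> str:
        return self.labels[self.keywords.index(keyword)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "label": self.labels}, index=self.keywords
        ).rename_axis("keyword")

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as handle:
            handle.write(f"# x_median={self.x_median!r},y_median={self.y_median!r}\n")
            self.to_frame().to_csv(handle)


def quadrant_label(x: float, y: float, x_median: float, y_median: float) -> str:
    if y > y_median:
        return STRONG if x >= x_median else WEAK
    return NOT_STRONG if x >= x_median else LATENT


def build_kim(keywords: Sequence[str],
              avg_df: Sequence[float],
              avg_growth: Sequence[float]) -> KimResult:
    """Place keywords on the issue map and label their quadrants.

    Medians are taken jointly over every supplied keyword (one map, one
    median split). Even counts use the standard midpoint of the two central
    order statistics. Requires at least 2 keywords.
    """
    keywords = list(keywords)
    x = np.asarray(avg_df, dtype=float)
    y = np.asarray(avg_growth, dtype=float)
    if len(keywords) < 2:
        raise ValueError("a keyword issue map needs at least 2 keywords")
    if x.shape != (len(keywords),) or y.shape != (len(keywords),):
        raise ValueError("avg_df and avg_growth must match the keyword count")
    x_median = float(np.median(x))
    y_median = float(np.median(y))
    labels = [quadrant_label(xi, yi, x_median, y_median) for xi, yi in zip(x, y)]
    return KimResult(keywords, x, y, x_median, y_median, labels)


def build_kim_from_metrics(metrics: pd.DataFrame) -> KimResult:
    """Build a KIM from a ``compute_signal_metrics`` table (uses the
    unrounded average DF as the x coordinate)."""
    return build_kim(list(metrics.index),
                     metrics["avg_df_exact"].to_numpy(),
                     metrics["avg_growth"].to_numpy())


def classify_signals(kim: KimResult) -> dict[str, list[str]]:
    """Group keywords by signal class, ordered by descending growth rate
    (stable in the original keyword order on ties)."""
    order = sorted(range(len(kim.keywords)), key=lambda i: -kim.y[i])
    grouped: dict[str, list[str]] = {label: [] for label in LABELS}
    for i in order:
        grouped[kim.labels[i]].append(kim.keywords[i])
    return grouped


def compare_labels(kim: KimResult,
                   reference: Mapping[str, str]) -> list[tuple[str, str, str]]:
    """Flag keywords whose computed quadrant disagrees with a reference
    classification. Returns (keyword, reference_label, computed_label)
    tuples; an empty list means full agreement."""
    mismatches = []
    for keyword, label in zip(kim.keywords, kim.labels):
        expected = reference.get(keyword)
        if expected is not None and expected != label:
            mismatches.append((keyword, expected, label))
    return mismatches


def plot_kim(kim: KimResult, path: str | Path,
             display_labels: Mapping[str, str] | None = None) -> None:
    """Scatter-plot export with median quadrant lines (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {STRONG: "tab:blue", WEAK: "tab:red",
              LATENT: "tab:gray", NOT_STRONG: "tab:green"}
    fig, ax = plt.subplots(figsize=(8, 6))
    for keyword, xi, yi, label in zip(kim.keywords, kim.x, kim.y, kim.labels):
        ax.scatter(xi, yi, color=colors[label], s=30)
        name = (display_labels or {}).get(keyword, keyword)
        ax.annotate(name, (xi, yi), fontsize=7, xytext=(3, 3),
                    textcoords="offset points")
    ax.axvline(kim.x_median, color="k", lw=0.8, ls="--")
    ax.axhline(kim.y_median, color="k", lw=0.8, ls="--")
    ax.set_xlabel("average DF")
    ax.set_ylabel("average DoD growth rate")
    ax.set_title("Keyword issue map")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
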