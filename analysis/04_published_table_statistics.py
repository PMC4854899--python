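#!/usr/bin/env python
"""Dose-response statistics recomputed from the published group summaries.

From printed mean/SEM/N alone: one-way ANOVA F per structure (SD
reconstructed as SEM*sqrt(N)), the top-dose percent-change columns, and
the sham normalized cortical fraction.  Writes results/published_stats.tsv.
"""

import os

import pandas as pd

from atlasvol import tables
from atlasvol.stats import anova_oneway, percent_change

os.makedirs("results", exist_ok=True)

absolute = tables.load_absolute_volume_summaries()
normalized = tables.load_normalized_volume_summaries()

rows = []
for structure in absolute["structure"].unique():
    summ = tables.summaries_for(absolute, structure)
    res = anova_oneway(summ)
    means = [s.mean for s in summ]
    rows.append({
        "structure": structure, "kind": "absolute",
        "F": res.F, "df_between": res.df_between, "df_within": res.df_within,
        "p": res.p,
        "pct_change_top_vs_control": percent_change(means[0], means[-1]),
    })
for structure in normalized["structure"].unique():
    summ = tables.summaries_for(normalized, structure)
    res = anova_oneway(summ)
    means = [s.mean for s in summ]
    direction = "increase" if means[-1] > means[0] else "decrease"
    rows.append({
        "structure": structure, "kind": "normalized",
        "F": res.F, "df_between": res.df_between, "df_within": res.df_within,
        "p": res.p,
        "pct_change_top_vs_control": percent_change(means[0], means[-1],
                                                    direction),
    })

df = pd.DataFrame(rows)
df.to_csv("results/published_stats.tsv", sep="\t", index=False)

key = df[df["structure"].isin(["total_brain", "cerebellum", "striatum",
                               "pons", "ventricles"])]
print(key[["structure", "kind", "F", "pct_change_top_vs_control"]]
      .round(2).to_string(index=False))
print(f"\ntotal N = {sum(tables.GROUP_SIZES)}, "
      f"df_within = {sum(tables.GROUP_SIZES) - len(tables.GROUP_SIZES)}")
print("full table -> results/published_stats.tsv")
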