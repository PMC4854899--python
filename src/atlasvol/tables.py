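"""Loaders for the packaged published group-summary tables.

The study's raw images and behavior logs are not deposited; what is
published are per-structure group summaries (mean ± SEM with group sizes
18/15/7/11/10 for 0.00/0.10/0.33/0.66/1.00 Gy) of absolute volumes (mm^3)
and normalized volumes (% of whole brain).  These tables are the inputs to
the summary-statistics layer and the reference against which the synthetic
cohort's dose-effect defaults are parameterized.
"""

from __future__ import annotations

import os

import pandas as pd

from .stats import GroupSummary

__all__ = [
    "DOSE_GROUPS_GY",
    "GROUP_SIZES",
    "load_absolute_volume_summaries",
    "load_normalized_volume_summaries",
    "summaries_for",
]

DOSE_GROUPS_GY = (0.00, 0.10, 0.33, 0.66, 1.00)
GROUP_SIZES = (18, 15, 7, 11, 10)

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def _load(name: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(_DATA_DIR, name), sep="\t")


def load_absolute_volume_summaries() -> pd.DataFrame:
    """Absolute regional volumes (mm^3): structure, dose_gy, n, mean, sem."""
    return _load("published_absolute_volumes.tsv")


def load_normalized_volume_summaries() -> pd.DataFrame:
    """Normalized regional volumes (% of whole brain)."""
    return _load("published_normalized_volumes.tsv")


def summaries_for(frame: pd.DataFrame, structure: str) -> list[GroupSummary]:
    """Rows for one structure as GroupSummary objects, ordered by dose."""
    sub = frame[frame["structure"] == structure].sort_values("dose_gy")
    if sub.empty:
        raise KeyError(f"no such structure in table: {structure!r}")
    return [
        GroupSummary(group=float(r.dose_gy), n=int(r.n), mean=float(r.mean),
                     sem=float(r.sem))
        for r in sub.itertuples()
    ]
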