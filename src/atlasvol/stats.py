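"""Group statistics for dose-response volumetry and behavior.

Implements the statistical layer of the study design: one-way ANOVA
computed either from raw per-subject values or reconstructed from printed
group summaries (mean, SEM, N — with SD_i = SEM_i * sqrt(N_i)), Bonferroni
post-hoc comparisons on the pooled within-group variance, one-sample
Student's t-tests (e.g. strategy use against the nine-strategy chance
level of 11.11%), and Pearson correlations with Benjamini–Hochberg
false-discovery-rate adjustment across the correlation family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "ANOVAResult",
    "CorrelationResult",
    "anova_oneway",
    "bonferroni_posthoc",
    "ttest_one_sample",
    "pearson_bh",
    "percent_change",
]


@dataclass
class GroupSummary:
    """Printed-table style group statistics: mean ± SEM with group size."""

    group: str | float
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.group!r}: N must be >= 2, got {self.n}")
        if self.sem < 0:
            raise ValueError(f"group {self.group!r}: SEM must be >= 0")

    @property
    def sd(self) -> float:
        """Standard deviation reconstructed as SEM * sqrt(N)."""
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_values(cls, group, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        n = len(values)
        return cls(group, n, float(values.mean()),
                   float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)


@dataclass
class ANOVAResult:
    F: float
    df_between: int
    df_within: int
    p: float
    infinite: bool = False  # zero within-group variance with unequal means


@dataclass
class CorrelationResult:
    label: str
    r: float
    p: float
    p_adjusted: float = float("nan")
    n: int = 0
    undefined: bool = False


def _is_summary_input(groups) -> bool:
    return all(isinstance(g, GroupSummary) for g in groups)


def anova_oneway(groups) -> ANOVAResult:
    """One-way fixed-effects ANOVA.

    Parameters
    ----------
    groups : list of array-like OR list of GroupSummary
        Raw per-subject values per group, or printed summaries.  The two
        forms must not be mixed.  Summary form reconstructs the within-group
        sum of squares from ``SD_i = SEM_i * sqrt(N_i)`` so that printed
        tables alone reproduce the F statistic.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    summary = _is_summary_input(groups)
    if not summary and any(isinstance(g, GroupSummary) for g in groups):
        raise TypeError("raw and summary inputs must not be mixed")

    if summary:
        ns = np.array([g.n for g in groups], dtype=float)
        means = np.array([g.mean for g in groups], dtype=float)
        sds = np.array([g.sd for g in groups], dtype=float)
    else:
        arrs = [np.asarray(g, dtype=float) for g in groups]
        ns = np.array([len(a) for a in arrs], dtype=float)
        if (ns < 2).any():
            raise ValueError("every group must have N >= 2")
        means = np.array([a.mean() for a in arrs])
        sds = np.array([a.std(ddof=1) for a in arrs])

    if (ns < 2).any():
        raise ValueError("every group must have N >= 2")

    k = len(ns)
    df_between = k - 1
    df_within = int(ns.sum()) - k
    grand_mean = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand_mean) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())

    ms_between = ss_between / df_between
    if ss_within == 0.0:
        if ss_between > 0:
            return ANOVAResult(math.inf, df_between, df_within, 0.0, infinite=True)
        return ANOVAResult(0.0, df_between, df_within, 1.0)
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return ANOVAResult(float(F), df_between, df_within, p)


def bonferroni_posthoc(groups, control_index: int = 0,
                       labels=None) -> pd.DataFrame:
    """Pairwise control-vs-group t-tests on the pooled within-group variance.

    Each two-sided p is multiplied by the number of comparisons and capped
    at 1 (Bonferroni).  Degrees of freedom come from the pooled variance
    (total N minus number of groups), matching the post-hoc convention of
    following a significant omnibus ANOVA.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group must have N >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    ns = np.array([len(a) for a in arrs], dtype=float)
    sds = np.array([a.std(ddof=1) for a in arrs])
    df_within = int(ns.sum()) - len(arrs)
    pooled_var = float(((ns - 1) * sds**2).sum() / df_within)

    others = [i for i in range(len(arrs)) if i != control_index]
    n_comp = len(others)
    rows = []
    ctrl = arrs[control_index]
    for i in others:
        se = math.sqrt(pooled_var * (1 / len(ctrl) + 1 / len(arrs[i])))
        if se == 0:
            t, p = (0.0, 1.0) if arrs[i].mean() == ctrl.mean() else (math.inf, 0.0)
        else:
            t = (arrs[i].mean() - ctrl.mean()) / se
            p = 2 * float(sps.t.sf(abs(t), df_within))
        rows.append({
            "comparison": f"{labels[control_index]} vs {labels[i]}",
            "t": t, "df": df_within, "p": p,
            "p_adjusted": min(1.0, p * n_comp),
        })
    return pd.DataFrame(rows)


def ttest_one_sample(values, reference: float) -> tuple[float, float]:
    """Classical one-sample t-test of ``values`` against a reference mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need n >= 2 for a one-sample t-test")
    if values.std(ddof=1) == 0.0:
        if values.mean() == reference:
            return 0.0, 1.0
        return math.inf, 0.0
    t, p = sps.ttest_1samp(values, reference)
    return float(t), float(p)


def pearson_bh(pairs, q: float = 0.05) -> list[CorrelationResult]:
    """Pearson r per (x, y) pair with Benjamini–Hochberg adjustment.

    Parameters
    ----------
    pairs : list of (label, x, y)
        Each x/y of equal length >= 3.  A pair with a constant vector gets
        an undefined-flagged result and is excluded from the BH family.
    q : float
        FDR level used for the ``significant`` call (default 0.05).
    """
    results: list[CorrelationResult] = []
    for label, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError(f"{label}: x and y lengths differ")
        if len(x) < 3:
            raise ValueError(f"{label}: need n >= 3")
        if x.std() == 0.0 or y.std() == 0.0:
            results.append(CorrelationResult(label, float("nan"), float("nan"),
                                             n=len(x), undefined=True))
            continue
        r, p = sps.pearsonr(x, y)
        results.append(CorrelationResult(label, float(r), float(p), n=len(x)))

    defined = [res for res in results if not res.undefined]
    if defined:
        adj = multipletests([res.p for res in defined], alpha=q,
                            method="fdr_bh")[1]
        for res, pa in zip(defined, adj):
            res.p_adjusted = float(max(pa, res.p))
    return results


def percent_change(reference: float, value: float, direction: str = "decrease") -> float:
    """Percent change between two group means.

    ``direction='decrease'`` reports 100*(reference - value)/reference (the
    convention of the absolute-volume table, where the printed column is the
    loss at the top dose relative to control); ``'increase'`` reports
    100*(value - reference)/reference (the normalized-ventricle convention).
    """
    if reference == 0:
        raise ValueError("reference mean is zero")
    if direction == "decrease":
        return 100.0 * (reference - value) / reference
    if direction == "increase":
        return 100.0 * (value - reference) / reference
    raise ValueError(f"unknown direction {direction!r}")
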