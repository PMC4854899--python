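"""Behavioral covariate tables with prescribed volume correlations.

Generates per-subject behavioral parameters whose population Pearson
correlation with a chosen volume measure equals a target r, with optional
per-dose-group mean shifts, expressed as percent-of-control — the
structure of the published brain–behavior correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..behavior_metrics import percent_of_control

__all__ = ["BehaviorTargets", "make_behavior"]


@dataclass
class BehaviorTargets:
    """One behavioral parameter tied to one volume measure.

    ``r`` is the target population correlation with the volume z-score;
    ``group_shifts`` are per-dose mean shifts in within-group SD units.
    """

    parameter: str
    volume_measure: str
    r: float
    group_shifts: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not abs(self.r) < 1:
            raise ValueError(f"|r| must be < 1, got {self.r}")


def make_behavior(volumes: pd.DataFrame, targets: list[BehaviorTargets],
                  seed: int = 0) -> pd.DataFrame:
    """Behavioral table correlated with per-subject volume measures.

    ``volumes`` is wide-format: one row per subject with columns
    ``subject_id``, ``dose_gy`` and one column per volume measure.  Each
    target parameter is built as ``r*z + sqrt(1-r^2)*noise`` on the volume
    z-score (population correlation r), plus group mean shifts, then
    rescaled to a positive behavioral scale and expressed as
    percent-of-control.
    """
    rng = np.random.default_rng(seed)
    out = volumes[["subject_id", "dose_gy"]].copy()
    for tgt in targets:
        if tgt.volume_measure not in volumes.columns:
            raise KeyError(f"volume measure {tgt.volume_measure!r} not in table")
        v = volumes[tgt.volume_measure].to_numpy(float)
        if v.std() == 0:
            raise ValueError(f"volume measure {tgt.volume_measure!r} is constant")
        z = (v - v.mean()) / v.std()
        eps = rng.standard_normal(len(z))
        latent = tgt.r * z + np.sqrt(1.0 - tgt.r**2) * eps
        for dose, shift in tgt.group_shifts.items():
            latent = latent + shift * np.isclose(
                volumes["dose_gy"].to_numpy(float), dose)
        raw = 100.0 + 15.0 * latent  # positive behavioral scale
        out[tgt.parameter] = raw
        out[tgt.parameter + "_pct_control"] = percent_of_control(
            out.assign(**{tgt.parameter: raw}), tgt.parameter)
    return out
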