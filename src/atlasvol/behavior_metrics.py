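"""Morris water maze search-strategy analysis and behavioral normalization.

Each swim trial is classified into one of nine substrategies in three
classes: spatial (spatial direct, spatial indirect, focal correct),
non-spatial systematic (scanning, random, focal incorrect) and repetitive
looping (chaining, peripheral looping, circling).  The published scheme is
a manual call; here it is a deterministic rule cascade on path features
(path efficiency, corridor occupancy toward the platform, scanned pool
area, focal-zone dwell at the target or a wrong focus, wall-band
occupancy, angular monotonicity and a platform-distance annulus for
chaining), with every threshold exposed in :class:`ClassifierConfig`.

Percent-of-strategy use is compared per substrategy against the
nine-strategy chance level of 100/9 = 11.11%, and behavioral parameters
are expressed as percent of the control-group mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ttest_one_sample

__all__ = [
    "PoolGeometry",
    "Trajectory",
    "StrategyCall",
    "ClassifierConfig",
    "CHANCE_LEVEL_PCT",
    "SUBSTRATEGY_CLASS",
    "classify_strategy",
    "strategy_percentages",
    "percent_of_control",
    "epm_ratios",
]

CHANCE_LEVEL_PCT = 100.0 / 9.0  # nine substrategies

SUBSTRATEGY_CLASS = {
    "spatial_direct": "spatial",
    "spatial_indirect": "spatial",
    "focal_correct": "spatial",
    "scanning": "non_spatial_systematic",
    "random": "non_spatial_systematic",
    "focal_incorrect": "non_spatial_systematic",
    "chaining": "repetitive_looping",
    "peripheral_looping": "repetitive_looping",
    "circling": "repetitive_looping",
}
STRATEGY_CLASSES = ("spatial", "non_spatial_systematic", "repetitive_looping")


@dataclass
class PoolGeometry:
    """Circular pool and hidden platform (study: 150 cm pool, 15 cm platform)."""

    center: tuple[float, float] = (0.0, 0.0)
    radius_cm: float = 75.0
    platform_center: tuple[float, float] = (26.52, 26.52)  # mid-NE quadrant
    platform_radius_cm: float = 7.5

    @property
    def platform_offset_cm(self) -> float:
        """Distance of the platform centre from the pool centre."""
        p = np.asarray(self.platform_center) - np.asarray(self.center)
        return float(np.hypot(*p))


@dataclass
class Trajectory:
    """Timestamped 2D swim track with pool/platform context."""

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    pool: PoolGeometry = field(default_factory=PoolGeometry)
    subject: str = ""
    day: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float)
        self.x_cm = np.asarray(self.x_cm, float)
        self.y_cm = np.asarray(self.y_cm, float)
        if not (len(self.t_s) == len(self.x_cm) == len(self.y_cm)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_s) >= 2 and not (np.diff(self.t_s) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        r = np.hypot(self.x_cm - self.pool.center[0],
                     self.y_cm - self.pool.center[1])
        if (r > self.pool.radius_cm + 1.0).any():
            raise ValueError("trajectory leaves the pool (beyond 1 cm tolerance)")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def resampled(self, rate_hz: float = 10.0) -> "Trajectory":
        """Uniformly resampled copy (linear interpolation)."""
        if self.duration_s <= 0:
            return self
        n = max(int(round(self.duration_s * rate_hz)) + 1, 2)
        tt = np.linspace(self.t_s[0], self.t_s[-1], n)
        return Trajectory(tt, np.interp(tt, self.t_s, self.x_cm),
                          np.interp(tt, self.t_s, self.y_cm),
                          pool=self.pool, subject=self.subject,
                          day=self.day, trial=self.trial)


@dataclass
class StrategyCall:
    substrategy: str
    strategy_class: str
    diagnostics: dict[str, float] = field(default_factory=dict)
    subject: str = ""
    day: int = 0
    trial: int = 0


@dataclass
class ClassifierConfig:
    """Thresholds of the rule cascade (documented defaults)."""

    resample_hz: float = 10.0
    corridor_halfwidth_cm: float = 15.0
    min_efficiency_direct: float = 0.7
    min_corridor_direct: float = 0.8
    min_efficiency_indirect: float = 0.3
    focal_zone_radius_cm: float = 15.0  # circle of 2x platform diameter
    min_focal_fraction: float = 0.4
    min_focal_separation_cm: float = 25.0
    wall_band_fraction: float = 0.15    # outer 15% of the pool radius
    min_wall_fraction: float = 0.8
    annulus_halfwidth_cm: float = 10.0
    min_annulus_fraction: float = 0.7
    scan_radius_cm: float = 12.0
    scan_cell_cm: float = 10.0
    min_scanned_fraction_scanning: float = 0.5
    min_scanned_fraction_random: float = 0.6
    centered_mean_radius_fraction: float = 0.55
    min_turn_monotonicity: float = 0.6
    min_turn_rate_deg_s: float = 80.0
    min_pool_rotation_turns: float = 1.0  # chaining must circle the pool


def _path_features(traj: Trajectory, cfg: ClassifierConfig) -> dict[str, float]:
    pool = traj.pool
    xy = np.stack([traj.x_cm, traj.y_cm], axis=1)
    ctr = np.asarray(pool.center)
    plat = np.asarray(pool.platform_center)
    steps = np.diff(xy, axis=0)
    seglen = np.hypot(steps[:, 0], steps[:, 1])
    path_len = float(seglen.sum())
    start = xy[0]
    ideal = max(float(np.linalg.norm(plat - start)) - pool.platform_radius_cm, 1e-6)
    efficiency = min(ideal / max(path_len, 1e-6), 1.0)

    # corridor occupancy: perpendicular distance to the start->platform segment
    seg = plat - start
    L2 = float(seg @ seg)
    tpar = np.clip((xy - start) @ seg / max(L2, 1e-12), 0.0, 1.0)
    proj = start + tpar[:, None] * seg
    corridor = float(np.mean(np.linalg.norm(xy - proj, axis=1)
                             <= cfg.corridor_halfwidth_cm))

    r = np.linalg.norm(xy - ctr, axis=1)
    wall_frac = float(np.mean(r >= (1.0 - cfg.wall_band_fraction) * pool.radius_cm))
    annulus_frac = float(np.mean(
        np.abs(r - pool.platform_offset_cm) <= cfg.annulus_halfwidth_cm))

    dist_plat = np.linalg.norm(xy - plat, axis=1)
    reached = bool((dist_plat <= pool.platform_radius_cm).any())
    focal_target = float(np.mean(dist_plat <= cfg.focal_zone_radius_cm))

    # best non-target focal zone: densest dwell around any sample far from
    # the platform (subsampled candidate centres)
    cand = xy[:: max(len(xy) // 60, 1)]
    cand = cand[np.linalg.norm(cand - plat, axis=1) >= cfg.min_focal_separation_cm]
    focal_other = 0.0
    if len(cand):
        d = np.linalg.norm(xy[None, :, :] - cand[:, None, :], axis=2)
        focal_other = float(np.max(np.mean(d <= cfg.focal_zone_radius_cm, axis=1)))

    # scanned pool-area fraction: cells within scan radius of any sample
    cell = cfg.scan_cell_cm
    nc = int(math.ceil(2 * pool.radius_cm / cell))
    ax = ctr[0] - pool.radius_cm + (np.arange(nc) + 0.5) * cell
    ay = ctr[1] - pool.radius_cm + (np.arange(nc) + 0.5) * cell
    cx, cy = np.meshgrid(ax, ay, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
    inside = np.linalg.norm(centers - ctr, axis=1) <= pool.radius_cm
    centers = centers[inside]
    d = np.linalg.norm(centers[:, None, :] - xy[None, :, :], axis=2)
    scanned = float(np.mean((d <= cfg.scan_radius_cm).any(axis=1)))
    centered = float(np.mean(r) <= cfg.centered_mean_radius_fraction * pool.radius_cm)

    # turning statistics
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    dh = np.diff(headings)
    dh = (dh + np.pi) % (2 * np.pi) - np.pi
    abs_turn = float(np.abs(dh).sum())
    monotonicity = float(abs(dh.sum()) / abs_turn) if abs_turn > 0 else 0.0
    turn_rate = float(np.degrees(np.abs(dh).mean()) * cfg.resample_hz) if len(dh) else 0.0

    # net revolutions of the pool-centre angle (chaining/looping signature)
    theta = np.arctan2(xy[:, 1] - ctr[1], xy[:, 0] - ctr[0])
    dth = np.diff(theta)
    dth = (dth + np.pi) % (2 * np.pi) - np.pi
    pool_turns = float(abs(dth.sum()) / (2 * np.pi))

    return {
        "path_length_cm": path_len, "efficiency": efficiency,
        "corridor_fraction": corridor, "wall_fraction": wall_frac,
        "annulus_fraction": annulus_frac, "reached_platform": float(reached),
        "focal_target_fraction": focal_target,
        "focal_other_fraction": focal_other,
        "scanned_fraction": scanned, "centered": centered,
        "turn_monotonicity": monotonicity, "turn_rate_deg_s": turn_rate,
        "pool_rotation_turns": pool_turns,
    }


def classify_strategy(traj: Trajectory,
                      config: ClassifierConfig | None = None) -> StrategyCall:
    """Deterministic rule cascade assigning one substrategy per trial."""
    cfg = config or ClassifierConfig()
    if len(traj.t_s) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    if traj.duration_s < 1.0:
        raise ValueError("trajectory shorter than 1 s")
    rt = traj.resampled(cfg.resample_hz)
    f = _path_features(rt, cfg)

    if f["wall_fraction"] >= cfg.min_wall_fraction:
        sub = "peripheral_looping"
    elif (f["turn_monotonicity"] >= cfg.min_turn_monotonicity
          and f["turn_rate_deg_s"] >= cfg.min_turn_rate_deg_s):
        sub = "circling"
    elif (f["efficiency"] >= cfg.min_efficiency_direct
          and f["corridor_fraction"] >= cfg.min_corridor_direct):
        sub = "spatial_direct"
    elif f["reached_platform"] and f["efficiency"] >= cfg.min_efficiency_indirect:
        sub = "spatial_indirect"
    elif f["focal_target_fraction"] >= cfg.min_focal_fraction:
        sub = "focal_correct"
    elif f["focal_other_fraction"] >= cfg.min_focal_fraction:
        sub = "focal_incorrect"
    elif (f["annulus_fraction"] >= cfg.min_annulus_fraction
          and f["pool_rotation_turns"] >= cfg.min_pool_rotation_turns):
        sub = "chaining"
    elif f["scanned_fraction"] >= cfg.min_scanned_fraction_scanning and f["centered"]:
        sub = "scanning"
    else:
        sub = "random"
    return StrategyCall(sub, SUBSTRATEGY_CLASS[sub], diagnostics=f,
                        subject=traj.subject, day=traj.day, trial=traj.trial)


def strategy_percentages(calls: list[StrategyCall],
                         chance_pct: float = CHANCE_LEVEL_PCT,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-day class/substrategy percentages and t-tests against chance.

    Returns ``(percentages, tests)``: percentages holds per-day percent of
    trials per strategy class and per substrategy (classes sum to 100% per
    day); tests holds, per (day, substrategy), the one-sample t of the
    per-subject percentages against the chance level (11.11%), when at
    least two subjects contribute.
    """
    if not calls:
        raise ValueError("no strategy calls given")
    df = pd.DataFrame([{
        "subject": c.subject, "day": c.day, "trial": c.trial,
        "substrategy": c.substrategy, "strategy_class": c.strategy_class,
    } for c in calls])

    pct_rows = []
    for day, sub in df.groupby("day"):
        n = len(sub)
        for cls in STRATEGY_CLASSES:
            pct_rows.append({"day": day, "level": "class", "name": cls,
                             "percent": 100.0 * (sub["strategy_class"] == cls).sum() / n})
        for s in SUBSTRATEGY_CLASS:
            pct_rows.append({"day": day, "level": "substrategy", "name": s,
                             "percent": 100.0 * (sub["substrategy"] == s).sum() / n})
    percentages = pd.DataFrame(pct_rows)

    test_rows = []
    for (day, s), _ in df.groupby(["day", "substrategy"]):
        per_subject = (
            df[df["day"] == day].groupby("subject")["substrategy"]
            .apply(lambda col: 100.0 * (col == s).mean())
        )
        if len(per_subject) >= 2 and per_subject.std(ddof=1) >= 0:
            try:
                t, p = ttest_one_sample(per_subject.to_numpy(), chance_pct)
            except ValueError:
                continue
            test_rows.append({"day": day, "substrategy": s,
                              "mean_percent": per_subject.mean(),
                              "t_vs_chance": t, "p": p,
                              "n_subjects": len(per_subject)})
    return percentages, pd.DataFrame(test_rows)


def percent_of_control(frame: pd.DataFrame, value_col: str,
                       group_col: str = "dose_gy",
                       control_group=0.0) -> pd.Series:
    """Express a per-subject parameter as percent of the control-group mean."""
    ctrl = frame.loc[frame[group_col] == control_group, value_col]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} is empty")
    m = ctrl.mean()
    if m == 0:
        raise ValueError("control-group mean is zero")
    return 100.0 * frame[value_col] / m


def epm_ratios(entries_open: int, entries_closed: int,
               ) -> tuple[float, float, bool]:
    """Elevated-plus-maze entry ratios.

    Returns ``(open/total %, open/closed ratio, ratio_defined)``; with zero
    closed-arm entries the ratio is flagged undefined (NaN) rather than
    infinite.
    """
    if entries_open < 0 or entries_closed < 0:
        raise ValueError("entry counts must be non-negative")
    total = entries_open + entries_closed
    if total == 0:
        raise ValueError("total entries must be > 0")
    pct = 100.0 * entries_open / total
    if entries_closed == 0:
        return pct, float("nan"), False
    return pct, entries_open / entries_closed, True
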