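"""Stochastic swim-path models for the nine search substrategies.

Each generator produces a 10 Hz trajectory inside the study pool geometry
(150 cm pool, 15 cm hidden platform mid-quadrant) with a swim speed around
20 cm/s: a direct corridor walk; a detoured approach through a waypoint;
focal circling at the target (or at a wrong focus); a space-filling
central scan; an uncorrelated persistent random walk; a fixed-radius
chaining annulus walk; a wall-following loop; and tight drifting circles.
Labels are ground truth for the classifier round-trip tests.
"""

from __future__ import annotations

import math

import numpy as np

from ..behavior_metrics import PoolGeometry, Trajectory

__all__ = ["SUBSTRATEGIES", "make_trajectories", "PoolGeometry"]

SUBSTRATEGIES = (
    "spatial_direct", "spatial_indirect", "focal_correct", "scanning",
    "random", "focal_incorrect", "chaining", "peripheral_looping", "circling",
)

_RATE_HZ = 10.0
_SPEED = 20.0  # cm/s


def _clip_to_pool(xy: np.ndarray, pool: PoolGeometry, margin: float = 1.5) -> np.ndarray:
    ctr = np.asarray(pool.center)
    d = xy - ctr
    r = np.hypot(d[:, 0], d[:, 1])
    rmax = pool.radius_cm - margin
    over = r > rmax
    if over.any():
        xy = xy.copy()
        xy[over] = ctr + d[over] * (rmax / r[over])[:, None]
    return xy


def _start_point(pool: PoolGeometry, rng: np.random.Generator) -> np.ndarray:
    # one of four release points at the wall, away from the platform quadrant
    ang = rng.choice([math.radians(a) for a in (135.0, 180.0, 225.0, 270.0)])
    r = 0.93 * pool.radius_cm
    return np.asarray(pool.center) + r * np.array([math.cos(ang), math.sin(ang)])


def _walk_heading(start, headings, speed, pool):
    steps = np.stack([np.cos(headings), np.sin(headings)], axis=1) * speed / _RATE_HZ
    xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
    return _clip_to_pool(xy, pool)


def _segment(p0, p1, speed=_SPEED, jitter=0.0, rng=None):
    d = np.linalg.norm(p1 - p0)
    n = max(int(round(d / speed * _RATE_HZ)), 2)
    line = np.linspace(0, 1, n)[:, None] * (p1 - p0) + p0
    if jitter > 0 and rng is not None:
        noise = rng.normal(0, jitter, size=(n, 2))
        noise[0] = noise[-1] = 0
        line = line + noise
    return line


def _gen_spatial_direct(pool, rng):
    start = _start_point(pool, rng)
    plat = np.asarray(pool.platform_center)
    return _segment(start, plat, jitter=0.4, rng=rng)


def _gen_spatial_indirect(pool, rng):
    start = _start_point(pool, rng)
    plat = np.asarray(pool.platform_center)
    mid = 0.5 * (start + plat)
    perp = np.array([-(plat - start)[1], (plat - start)[0]])
    perp /= max(np.linalg.norm(perp), 1e-9)
    way = mid + perp * rng.uniform(18.0, 30.0) * rng.choice([-1, 1])
    way = _clip_to_pool(way[None, :], pool, margin=8.0)[0]
    xy = np.vstack([_segment(start, way, jitter=1.5, rng=rng),
                    _segment(way, plat, jitter=1.5, rng=rng)])
    return xy


def _focal(pool, rng, around, dwell_s=18.0):
    start = _start_point(pool, rng)
    approach = _segment(start, around, jitter=1.5, rng=rng)
    n = int(dwell_s * _RATE_HZ)
    pos = around.copy()
    pts = []
    for _ in range(n):
        pos = pos + rng.normal(0, 1.0, 2) * _SPEED * 0.35 / _RATE_HZ * 2.0
        # soft pull back toward the focus
        pos = around + (pos - around) * 0.92
        pts.append(pos.copy())
    return _clip_to_pool(np.vstack([approach, pts]), pool)


def _gen_focal_correct(pool, rng):
    return _focal(pool, rng, np.asarray(pool.platform_center))


def _gen_focal_incorrect(pool, rng):
    wrong = -np.asarray(pool.platform_center)  # mirrored through the centre
    return _focal(pool, rng, wrong, dwell_s=25.0)


def _gen_scanning(pool, rng):
    # lawnmower sweeps across the central region
    ctr = np.asarray(pool.center)
    half = 0.62 * pool.radius_cm
    ys = np.linspace(-half, half, 7)
    if rng.random() < 0.5:
        ys = ys[::-1]
    pts = [_start_point(pool, rng)]
    for i, y in enumerate(ys):
        xr = math.sqrt(max(half**2 - y**2, 25.0))
        x0, x1 = (-xr, xr) if i % 2 == 0 else (xr, -xr)
        pts.append(ctr + np.array([x0, y]))
        pts.append(ctr + np.array([x1, y]))
    segs = [_segment(pts[i], pts[i + 1], jitter=1.0, rng=rng)
            for i in range(len(pts) - 1)]
    return _clip_to_pool(np.vstack(segs), pool)


def _gen_random(pool, rng):
    start = _start_point(pool, rng)
    n = int(60.0 * _RATE_HZ)
    headings = np.cumsum(rng.normal(0, math.radians(35.0), n))
    headings += rng.uniform(0, 2 * math.pi)
    xy = [start]
    ctr = np.asarray(pool.center)
    pos = start.copy()
    for h in headings:
        step = np.array([math.cos(h), math.sin(h)]) * _SPEED / _RATE_HZ
        pos = pos + step
        d = pos - ctr
        r = np.hypot(*d)
        if r > pool.radius_cm - 2.0:
            pos = ctr + d * ((pool.radius_cm - 2.0) / r)
        xy.append(pos.copy())
    return np.asarray(xy)


def _annulus_walk(pool, rng, radius, revolutions, radial_sd):
    ctr = np.asarray(pool.center)
    ang0 = rng.uniform(0, 2 * math.pi)
    total = revolutions * 2 * math.pi * rng.choice([-1, 1])
    n = max(int(abs(total) * radius / _SPEED * _RATE_HZ), 20)
    ang = ang0 + np.linspace(0, total, n)
    # mean-reverting radial wobble keeps the path tight to the annulus
    dev = np.empty(n)
    d = 0.0
    for i, e in enumerate(rng.normal(0, radial_sd, n)):
        d = 0.85 * d + e
        dev[i] = d
    rr = radius + dev
    xy = ctr + np.stack([rr * np.cos(ang), rr * np.sin(ang)], axis=1)
    return _clip_to_pool(xy, pool)


def _gen_chaining(pool, rng):
    return _annulus_walk(pool, rng, pool.platform_offset_cm,
                         rng.uniform(1.5, 2.5), radial_sd=0.8)


def _gen_peripheral(pool, rng):
    return _annulus_walk(pool, rng, 0.92 * pool.radius_cm,
                         rng.uniform(1.2, 2.0), radial_sd=0.5)


def _gen_circling(pool, rng):
    ctr = np.asarray(pool.center)
    focus = ctr + rng.uniform(-0.3, 0.3, 2) * pool.radius_cm
    n = int(40.0 * _RATE_HZ)
    radius = rng.uniform(7.0, 10.0)
    omega = _SPEED / radius / _RATE_HZ * rng.choice([-1, 1])
    ang = rng.uniform(0, 2 * math.pi) + omega * np.arange(n)
    drift = np.cumsum(rng.normal(0, 0.25, size=(n, 2)), axis=0)
    xy = focus + drift + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    return _clip_to_pool(xy, pool)


_GENERATORS = {
    "spatial_direct": _gen_spatial_direct,
    "spatial_indirect": _gen_spatial_indirect,
    "focal_correct": _gen_focal_correct,
    "scanning": _gen_scanning,
    "random": _gen_random,
    "focal_incorrect": _gen_focal_incorrect,
    "chaining": _gen_chaining,
    "peripheral_looping": _gen_peripheral,
    "circling": _gen_circling,
}


def make_trajectories(substrategy: str, n: int,
                      pool: PoolGeometry | None = None,
                      seed: int = 0) -> list[Trajectory]:
    """Generate ``n`` labeled trajectories of one substrategy."""
    if substrategy not in _GENERATORS:
        raise ValueError(f"unknown substrategy {substrategy!r}; "
                         f"choose from {sorted(_GENERATORS)}")
    pool = pool or PoolGeometry()
    rng = np.random.default_rng(np.random.SeedSequence([seed, SUBSTRATEGIES.index(substrategy)]))
    out = []
    for i in range(n):
        xy = _GENERATORS[substrategy](pool, rng)
        t = np.arange(len(xy)) / _RATE_HZ
        out.append(Trajectory(t, xy[:, 0], xy[:, 1], pool=pool,
                              subject=f"{substrategy}-{i:02d}", trial=i))
    return out
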