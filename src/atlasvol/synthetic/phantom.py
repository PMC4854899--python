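"""Digital brain phantoms with known regional volumes.

The synthetic atlas is a brain-shaped ellipsoid partitioned into the 19
structures of interest: the ventricles are a central ellipsoid (so their
volume has a closed form for analytic checks) and the remaining tissue is
divided by a multiplicatively-weighted Voronoi partition whose weights are
set from the sham-group normalized volume fractions of the published
tables, giving structures of realistic relative size.  Sub-labels (39 in
total: four ventricle compartments, left/right splits, one midline
structure) reproduce the label-merge bookkeeping of the real atlas.

Dose-effect cohorts regenerate the parametric geometry per subject — a
global volumetric scale per dose group (the ratio of published whole-brain
group means), per-structure relative multipliers (ratios of published
normalized means), an optional dorsal third-ventricle protrusion at the
top dose — then apply a random smooth B-spline warp, a multiplicative
bias field, and additive Gaussian noise to the intensity image.  Ground
truth volumes are counted from the warped label map before any intensity
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ..image_io import LabelMap, LabelTable, VolumeImage, load_study_label_table
from ..registration import FFDTransform, TransformChain, ffd_for_geometry, resample
from ..volumetry import RegionVolumeRecord
from .. import tables

__all__ = [
    "PhantomSpec",
    "DoseEffectSpec",
    "CohortSubject",
    "make_phantom_atlas",
    "make_cohort",
    "study_dose_effects",
    "demo_dose_effects",
]

# structure ids follow the packaged merge table
STRUCTURES = {
    1: "ventricles", 2: "posterior_cerebral_cortex", 3: "hippocampus",
    4: "olfactory_system", 5: "frontal_cortex", 6: "striatum", 7: "thalamus",
    8: "midbrain", 9: "basal_ganglia", 10: "corpus_callosum", 11: "amygdala",
    12: "hypothalamus", 13: "cerebellum", 14: "pons", 15: "medulla",
    16: "fornix_system", 17: "anterior_commissure", 18: "corpora_quadrigemina",
    19: "internal_capsule",
}
NAME_TO_ID = {v: k for k, v in STRUCTURES.items()}

# sham-group normalized volume fractions (% of whole brain) driving the
# weighted Voronoi partition; anterior/posterior placement is loosely
# anatomical so the phantom has a recognisable front/back organisation
_SEEDS = {
    # name: (fraction %, unit offset within brain semi-axes)
    "posterior_cerebral_cortex": (22.8, (0.0, -0.35, 0.55)),
    "olfactory_system": (10.4, (0.0, 0.85, -0.10)),
    "cerebellum": (10.9, (0.0, -0.85, 0.10)),
    "midbrain": (6.2, (0.0, -0.45, -0.10)),
    "pons": (6.2, (0.0, -0.55, -0.55)),
    "medulla": (5.4, (0.0, -0.90, -0.45)),
    "hippocampus": (5.0, (0.45, -0.20, 0.25)),
    "striatum": (4.5, (0.50, 0.30, 0.05)),
    "thalamus": (3.9, (0.30, -0.05, 0.05)),
    "frontal_cortex": (3.6, (0.0, 0.55, 0.55)),
    "corpora_quadrigemina": (3.4, (0.0, -0.30, 0.45)),
    "amygdala": (3.2, (0.65, 0.10, -0.45)),
    "corpus_callosum": (2.2, (0.0, 0.15, 0.45)),
    "basal_ganglia": (2.1, (0.55, 0.15, -0.25)),
    "hypothalamus": (1.8, (0.0, 0.15, -0.60)),
    "fornix_system": (1.1, (0.20, 0.05, 0.25)),
    "internal_capsule": (1.1, (0.40, 0.10, 0.15)),
    "anterior_commissure": (0.7, (0.0, 0.40, -0.30)),
}

# distinct per-structure T2-like contrast (arbitrary units); CSF bright.
# Levels alternate between spatially adjacent structures so every internal
# boundary carries a step well above the noise scale
_INTENSITY = {
    "ventricles": 240.0, "posterior_cerebral_cortex": 77.0,
    "hippocampus": 131.0, "olfactory_system": 174.0, "frontal_cortex": 120.0,
    "striatum": 99.0, "thalamus": 196.0, "midbrain": 45.0,
    "basal_ganglia": 153.0, "corpus_callosum": 217.0, "amygdala": 88.0,
    "hypothalamus": 142.0, "cerebellum": 228.0, "pons": 206.0,
    "medulla": 110.0, "fornix_system": 56.0, "anterior_commissure": 67.0,
    "corpora_quadrigemina": 163.0, "internal_capsule": 185.0,
}
_BACKGROUND = 20.0


@dataclass
class PhantomSpec:
    """Parameterization of the synthetic labeled atlas."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 0.16
    brain_semiaxes_vox: tuple[float, float, float] = (26.0, 22.0, 20.0)
    ventricle_semiaxes_vox: tuple[float, float, float] = (10.5, 7.0, 6.4)
    noise_sd: float = 0.0
    smooth_vox: float = 0.6  # partial-volume-like smoothing of intensities
    min_structure_voxels: int = 50
    seed: int = 0


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _build_structure_map(spec: PhantomSpec, global_scale: float = 1.0,
                         structure_multipliers: dict[str, float] | None = None,
                         protrusion: bool = False) -> np.ndarray:
    """19-structure label map from the parametric geometry.

    ``global_scale`` is a linear scale on all semi-axes (volume scales with
    its cube); ``structure_multipliers`` are relative volume multipliers
    applied to the ventricle ellipsoid and to the Voronoi weights.
    """
    mult = dict(structure_multipliers or {})
    shape = spec.dims
    center = (np.asarray(shape, float) - 1) / 2.0
    brain_ax = np.asarray(spec.brain_semiaxes_vox) * global_scale
    brain = _ellipsoid_mask(shape, center, brain_ax)

    def _vent_mask(linear_mult: float) -> np.ndarray:
        ax = np.asarray(spec.ventricle_semiaxes_vox) * global_scale * linear_mult
        v = _ellipsoid_mask(shape, center, ax)
        if protrusion:
            # dorsal protrusion of the third ventricle compartment
            bump_c = center + np.array([0.0, 0.0, ax[2] * 0.9])
            bump_ax = np.array([ax[0] * 0.45, ax[1] * 0.45, ax[2] * 0.9])
            v |= _ellipsoid_mask(shape, bump_c, bump_ax) & brain
        return v

    vent_mult = mult.get("ventricles", 1.0) ** (1.0 / 3.0)
    vent = _vent_mask(vent_mult)
    if protrusion:
        # the published relative enlargement already includes the dorsal
        # swelling, so shrink the ellipsoid until ellipsoid + bump meet the
        # same total-volume budget as the plain multiplier would
        target = (4.0 / 3.0) * np.pi * np.prod(
            np.asarray(spec.ventricle_semiaxes_vox) * global_scale * vent_mult)
        m = vent_mult
        for _ in range(3):
            count = _vent_mask(m).sum()
            m *= (target / max(count, 1)) ** (1.0 / 3.0)
        vent = _vent_mask(m)

    out = np.zeros(shape, dtype=np.int32)
    out[vent & brain] = NAME_TO_ID["ventricles"]

    tissue = brain & ~vent
    vox = np.argwhere(tissue).astype(float)
    names = list(_SEEDS)
    targets = np.array([_SEEDS[n][0] * mult.get(n, 1.0) for n in names])
    targets = targets / targets.sum()
    seeds = np.stack([center + np.asarray(_SEEDS[n][1]) * brain_ax * 0.75
                      for n in names])
    mirrored = seeds.copy()
    mirrored[:, 0] = 2 * center[0] - mirrored[:, 0]  # bilateral structures
    d2 = np.minimum(
        ((vox[None, :, :] - seeds[:, None, :]) ** 2).sum(axis=2),
        ((vox[None, :, :] - mirrored[:, None, :]) ** 2).sum(axis=2))
    # capacity-calibrated power diagram: adjust additive weights toward the
    # target fractions, then enforce exact voxel quotas by deferred
    # acceptance (each structure keeps its nearest claimants, bumping the
    # rest), so every structure's voxel share matches its target exactly
    w = np.zeros(len(names))
    eta0 = float(brain_ax.max()) ** 2
    best_err, best_w = np.inf, w.copy()
    for it in range(60):
        assign = np.argmin(d2 - w[:, None], axis=0)
        actual = np.bincount(assign, minlength=len(names)) / len(vox)
        err = targets - actual
        worst = float(np.abs(err).max())
        if worst < best_err:
            best_err, best_w = worst, w.copy()
        w = w + eta0 / (1 + it / 20) * err
        w -= w.mean()
    cost = d2 - best_w[:, None]
    quotas = _exact_quotas(targets, len(vox))
    assign = _deferred_acceptance(cost, quotas)
    ids = np.array([NAME_TO_ID[n] for n in names], dtype=np.int32)
    out[tuple(np.argwhere(tissue).T)] = ids[assign]
    return out


def _exact_quotas(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of target fractions to integer counts."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _deferred_acceptance(cost: np.ndarray, quotas: np.ndarray) -> np.ndarray:
    """Stable capacity-constrained assignment of voxels to structures.

    Every voxel proposes to structures in increasing cost order; a full
    structure keeps only its cheapest claimants.  Deterministic; terminates
    because bumped voxels only move down their preference lists.
    """
    n_s, n_v = cost.shape
    pref = np.argsort(cost, axis=0)  # per-voxel ranking of structures
    ptr = np.zeros(n_v, dtype=int)
    assigned = np.full(n_v, -1, dtype=int)
    members: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(n_s)]
    pending = np.arange(n_v)
    while len(pending):
        choice = pref[ptr[pending], pending]
        bumped = []
        for s in range(n_s):
            claim = pending[choice == s]
            if not len(claim):
                continue
            pool = np.concatenate([members[s], claim])
            if len(pool) > quotas[s]:
                keep_idx = np.argsort(cost[s, pool], kind="stable")[:quotas[s]]
                keep = pool[keep_idx]
                out_mask = np.ones(len(pool), dtype=bool)
                out_mask[keep_idx] = False
                rejected = pool[out_mask]
                bumped.append(rejected)
            else:
                keep = pool
            members[s] = keep
            assigned[keep] = s
        if bumped:
            pending = np.concatenate(bumped)
            assigned[pending] = -1
            ptr[pending] += 1
            ptr = np.minimum(ptr, n_s - 1)
        else:
            pending = np.empty(0, dtype=int)
    return assigned


def _split_39(merged: np.ndarray, table: LabelTable) -> np.ndarray:
    """Split 19 structures into the 39 atlas sub-labels.

    Left/right structures split at the mid-sagittal plane; the four
    ventricle compartments split by quadrant around the structure centroid;
    midline single-label structures pass through.
    """
    out = np.zeros_like(merged)
    df = table.frame
    cx = (merged.shape[0] - 1) / 2.0
    gx = np.arange(merged.shape[0])[:, None, None]
    for sid, sub in df.groupby("structure_id"):
        region = merged == sid
        if not region.any():
            continue
        labels = sub["label_id"].tolist()
        if len(labels) == 1:
            out[region] = labels[0]
        elif len(labels) == 2:  # left / right
            left = region & (gx < cx)
            out[region] = labels[1]
            out[left] = labels[0]
        else:  # ventricle compartments: quadrants in (y, z) around centroid
            com = ndimage.center_of_mass(region)
            gy = np.arange(merged.shape[1])[None, :, None]
            gz = np.arange(merged.shape[2])[None, None, :]
            quad = ((gy >= com[1]).astype(int) * 2
                    + (gz >= com[2]).astype(int)) * np.ones_like(merged)
            for q, lab in enumerate(labels[:4]):
                out[region & (quad == q)] = lab
    return out


def _intensity_from_labels(merged: np.ndarray, spec: PhantomSpec,
                           rng: np.random.Generator | None = None,
                           bias: np.ndarray | None = None) -> np.ndarray:
    img = np.full(merged.shape, _BACKGROUND, dtype=float)
    for sid, name in STRUCTURES.items():
        img[merged == sid] = _INTENSITY[name]
    if spec.smooth_vox > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.smooth_vox)
    if bias is not None:
        img = img * bias
    if rng is not None and spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        img = np.clip(img, 0.5, None)
    return img


def make_phantom_atlas(spec: PhantomSpec | None = None,
                       ) -> tuple[VolumeImage, LabelMap, LabelTable]:
    """Deterministic synthetic atlas: intensity image, 39-label map, table."""
    spec = spec or PhantomSpec()
    table = load_study_label_table()
    merged = _build_structure_map(spec)
    census = np.bincount(merged.ravel())
    small = [STRUCTURES[s] for s in STRUCTURES if census[s] < spec.min_structure_voxels]
    if small:
        raise ValueError(f"structures below {spec.min_structure_voxels} voxels: {small}")
    labels39 = _split_39(merged, table)
    img = _intensity_from_labels(merged, spec)
    sp = (spec.spacing_mm,) * 3
    return (VolumeImage(img, spacing=sp),
            LabelMap(labels39, spacing=sp),
            table)


# ---------------------------------------------------------------------------
# dose-effect cohorts
# ---------------------------------------------------------------------------

@dataclass
class DoseEffectSpec:
    """Per-group effect structure for the synthetic cohort.

    ``volume_scales`` are whole-brain volume factors relative to control;
    ``structure_multipliers`` are relative (normalized-volume) factors per
    structure and group.  Defaults are derived from the published tables
    by :func:`study_dose_effects`.
    """

    doses_gy: tuple[float, ...]
    group_sizes: tuple[int, ...]
    volume_scales: tuple[float, ...]
    structure_multipliers: dict[float, dict[str, float]] = field(default_factory=dict)
    warp_amplitude_vox: float = 1.0
    warp_spacing_vox: float = 12.0
    bias_amplitude: float = 0.10
    noise_sd: float = 4.0
    subject_volume_cv: float = 0.035
    protrusion_top_dose: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.doses_gy) == len(self.group_sizes) == len(self.volume_scales)):
            raise ValueError("doses, group sizes and scales must align")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if any(s <= 0 for s in self.volume_scales):
            raise ValueError("volume scale factors must be > 0")


def _published_multipliers(doses: tuple[float, ...]) -> dict[float, dict[str, float]]:
    norm = tables.load_normalized_volume_summaries()
    out: dict[float, dict[str, float]] = {}
    ctrl = norm[norm["dose_gy"] == 0.0].set_index("structure")["mean"]
    for d in doses:
        sub = norm[np.isclose(norm["dose_gy"], d)].set_index("structure")["mean"]
        out[d] = {s: float(sub[s] / ctrl[s]) for s in sub.index}
    return out


def study_dose_effects(seed: int = 0) -> DoseEffectSpec:
    """The full study conditions: 5 dose groups sized 18/15/7/11/10.

    Whole-brain scale factors are the ratios of the published whole-brain
    group means; per-structure multipliers the ratios of published
    normalized means.
    """
    absolute = tables.load_absolute_volume_summaries()
    wb = absolute[absolute["structure"] == "total_brain"].sort_values("dose_gy")
    scales = tuple(float(m / wb["mean"].iloc[0]) for m in wb["mean"])
    doses = tables.DOSE_GROUPS_GY
    return DoseEffectSpec(
        doses_gy=doses,
        group_sizes=tables.GROUP_SIZES,
        volume_scales=scales,
        structure_multipliers=_published_multipliers(doses),
        seed=seed,
    )


def demo_dose_effects(seed: int = 0) -> DoseEffectSpec:
    """Pipeline-scale cohort: 3 dose groups (0.00/0.66/1.00 Gy) sized 6/5/5.

    Effect sizes are the same published ratios as the full study; only the
    group structure is reduced so the full template + volumetry pipeline
    runs end-to-end in minutes on one CPU.
    """
    full = study_dose_effects(seed=seed)
    keep = (0.00, 0.66, 1.00)
    idx = [full.doses_gy.index(d) for d in keep]
    return replace(
        full,
        doses_gy=keep,
        group_sizes=(6, 5, 5),
        volume_scales=tuple(full.volume_scales[i] for i in idx),
        structure_multipliers={d: full.structure_multipliers[d] for d in keep},
    )


@dataclass
class CohortSubject:
    subject_id: str
    dose_gy: float
    image: VolumeImage
    true_labels: LabelMap  # merged 19-structure ground truth
    truth: RegionVolumeRecord


def _random_ffd(geometry: VolumeImage, amplitude_vox: float,
                spacing_vox: float, rng: np.random.Generator) -> FFDTransform:
    ffd = ffd_for_geometry(geometry, spacing_vox)
    amp_mm = amplitude_vox * min(geometry.spacing)
    coeff = rng.uniform(-amp_mm, amp_mm, size=ffd.coefficients.shape)
    return FFDTransform(ffd.origin, ffd.spacing, coeff)


def _smooth_bias(geometry: VolumeImage, amplitude: float,
                 rng: np.random.Generator) -> np.ndarray:
    axes = [np.linspace(-1, 1, n) for n in geometry.dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    c = rng.uniform(-1, 1, size=6)
    f = c[0] * gx + c[1] * gy + c[2] * gz + c[3] * gx * gy + c[4] * gy * gz + c[5] * gx * gz
    f = f / max(np.abs(f).max(), 1e-12) * amplitude
    return 1.0 + f


def make_cohort(spec: PhantomSpec | None = None,
                effects: DoseEffectSpec | None = None) -> list[CohortSubject]:
    """Generate a dose-effect cohort with ground-truth volumes.

    Per subject: sample a volumetric scale around the group factor, rebuild
    the parametric label geometry with the group's structure multipliers,
    apply a random smooth warp (ground truth counted *after* warping),
    then simulate intensities with bias field and additive noise.
    """
    spec = spec or PhantomSpec()
    effects = effects or study_dose_effects()
    rng = np.random.default_rng(effects.seed)
    sp = (spec.spacing_mm,) * 3
    geometry = VolumeImage(np.zeros(spec.dims), spacing=sp)
    top = max(effects.doses_gy)
    subjects: list[CohortSubject] = []
    for dose, n, vol_scale in zip(effects.doses_gy, effects.group_sizes,
                                  effects.volume_scales):
        mult = effects.structure_multipliers.get(dose, {})
        for i in range(n):
            subj_vol = vol_scale * float(
                np.exp(rng.normal(0.0, effects.subject_volume_cv)))
            lin_scale = subj_vol ** (1.0 / 3.0)
            protr = (effects.protrusion_top_dose and dose == top and dose > 0)
            merged = _build_structure_map(spec, global_scale=lin_scale,
                                          structure_multipliers=mult,
                                          protrusion=protr)
            labels = LabelMap(merged, spacing=sp)
            if effects.warp_amplitude_vox > 0:
                warp = _random_ffd(geometry, effects.warp_amplitude_vox,
                                   effects.warp_spacing_vox, rng)
                labels = resample(labels, TransformChain([warp]), geometry,
                                  interp="nearest")
            bias = _smooth_bias(geometry, effects.bias_amplitude, rng) \
                if effects.bias_amplitude > 0 else None
            noisy_spec = replace(spec, noise_sd=effects.noise_sd)
            img = _intensity_from_labels(labels.data, noisy_spec, rng=rng,
                                         bias=bias)
            sid = f"sub-{dose:.2f}Gy-{i:02d}"
            truth = _truth_record(labels, dose, sid)
            subjects.append(CohortSubject(sid, dose,
                                          VolumeImage(img, spacing=sp),
                                          labels, truth))
    return subjects


def _truth_record(labels: LabelMap, dose: float, sid: str) -> RegionVolumeRecord:
    vv = labels.voxel_volume
    absolute = {STRUCTURES[s]: c * vv for s, c in labels.label_census().items()}
    return RegionVolumeRecord(sid, dose, absolute, sum(absolute.values()))
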