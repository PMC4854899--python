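"""Stage-1 pre-processing of structural brain MR volumes.

Three steps, applied in order before any cross-subject registration:

1. intra-scan inhomogeneity (bias field) correction — a smooth
   multiplicative field estimated as a low-order 3D polynomial fit to the
   log-intensities inside the brain mask;
2. brain masking — the nonzero support of an atlas label map resampled
   into the subject grid and morphologically dilated (study value: three
   voxels, ball structuring element);
3. cross-subject linear intensity normalization — a per-image affine
   intensity map sending the masked 1st/99th percentiles onto those of a
   reference subject (the first of the cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import LabelMap, VolumeImage
from .registration import resample

__all__ = [
    "BiasField",
    "correct_bias",
    "ball_structuring_element",
    "make_brain_mask",
    "normalize_intensities",
]


@dataclass
class BiasField:
    """Multiplicative smooth field on the image grid, mean 1 in the mask."""

    field: np.ndarray
    order: int

    def __post_init__(self) -> None:
        if (self.field <= 0).any():
            raise ValueError("bias field must be strictly positive")


def _polynomial_design(shape: tuple[int, int, int], order: int) -> np.ndarray:
    """Design matrix of all 3D monomials x^i y^j z^k with i+j+k <= order."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((gx**i * gy**j * gz**k).ravel())
    return np.stack(cols, axis=1)


def correct_bias(img: VolumeImage, mask: np.ndarray,
                 order: int = 2) -> tuple[VolumeImage, BiasField]:
    """Divide out a smooth multiplicative intensity inhomogeneity.

    The field is fitted by least squares in the log-intensity domain as a
    polynomial of total degree ``order`` (default 2) within the mask, then
    gauge-fixed to mean 1 inside the mask so corrected intensities keep
    their scale.

    Raises if the mask is empty or contains non-positive intensities
    (log-domain fitting needs a positive offset added first).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    data = np.asarray(img.data, float)
    if (data[mask] <= 0).any():
        raise ValueError(
            "non-positive intensities inside the mask; add a positive offset "
            "before log-domain bias fitting"
        )
    X = _polynomial_design(data.shape, order)
    logv = np.log(data.ravel())
    sel = mask.ravel()
    coef, *_ = np.linalg.lstsq(X[sel], logv[sel], rcond=None)
    logfield = (X @ coef).reshape(data.shape)
    # the polynomial is only constrained inside the mask; clamp the
    # extrapolated field outside to the masked range so background
    # intensities are not blown up
    lo, hi = logfield[mask].min(), logfield[mask].max()
    field = np.exp(np.clip(logfield, lo, hi))
    field /= field[mask].mean()  # gauge: mean 1 within the mask
    corrected = img.copy_with(data / field)
    return corrected, BiasField(field, order)


def ball_structuring_element(radius: int) -> np.ndarray:
    """Discrete Euclidean ball: offsets with ||delta||_2 <= radius."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (gx**2 + gy**2 + gz**2) <= r**2


def make_brain_mask(atlas_labels: LabelMap, atlas_to_subject,
                    subject_geometry: VolumeImage,
                    dilation_voxels: int = 3) -> np.ndarray:
    """Brain mask from atlas labels resampled to the subject grid.

    ``atlas_to_subject`` maps subject-world points into atlas-world points
    (the pull-back convention: typically the inverse of an estimated
    atlas-to-subject affine, or an identity/None when grids coincide).
    The resampled nonzero-label support is dilated by ``dilation_voxels``
    with a Euclidean-ball structuring element (study default 3).
    """
    if dilation_voxels < 0:
        raise ValueError("dilation_voxels must be non-negative")
    labels_sub = resample(atlas_labels, atlas_to_subject, subject_geometry,
                          interp="nearest")
    mask = labels_sub.data > 0
    if not mask.any():
        raise ValueError(
            "resampled atlas labels have empty support in the subject grid "
            "(registration failure?)"
        )
    if dilation_voxels > 0:
        mask = ndimage.binary_dilation(
            mask, structure=ball_structuring_element(dilation_voxels))
    return mask


def normalize_intensities(imgs: list[VolumeImage], masks: list[np.ndarray],
                          percentiles: tuple[float, float] = (1.0, 99.0),
                          ) -> list[VolumeImage]:
    """Affine intensity normalization across subjects.

    Per image, a map a*I + b sends its masked low/high percentiles onto the
    reference values, where the reference is the first image of the cohort.
    Robust to gain/offset differences between scans; invariant (up to the
    reference) to any per-image affine intensity change.
    """
    if len(imgs) != len(masks):
        raise ValueError("need one mask per image")
    if not imgs:
        return []
    lo_p, hi_p = percentiles
    refs = None
    out = []
    for img, mask in zip(imgs, masks):
        mask = np.asarray(mask, bool)
        vals = np.asarray(img.data, float)[mask]
        lo, hi = np.percentile(vals, [lo_p, hi_p])
        if hi == lo:
            raise ValueError("degenerate intensity range within mask (p_lo == p_hi)")
        if refs is None:
            refs = (lo, hi)
            out.append(img.copy_with(np.asarray(img.data, float)))
            continue
        a = (refs[1] - refs[0]) / (hi - lo)
        b = refs[0] - a * lo
        out.append(img.copy_with(a * np.asarray(img.data, float) + b))
    return out
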