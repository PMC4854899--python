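"""Volumetric image and label-resource I/O.

All volumetric data moves through NIfTI-1 (.nii / .nii.gz) and is resolved
to a canonical RAS axis order on load, so every downstream stage can assume
one orientation convention.  Voxel indices are 0-based; world coordinates
are continuous millimetres with voxel centres at ``origin + index*spacing``,
which makes ``volume = count * prod(spacing)`` exact.

Label tables describing how atlas labels merge into structures of interest
are tab-separated text with a header row (columns: label_id, label_name,
structure_id, structure_name).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "LabelMap",
    "LabelTable",
    "read_volume",
    "write_volume",
    "read_label_table",
    "write_label_table",
    "load_study_label_table",
]

LABEL_TABLE_COLUMNS = ["label_id", "label_name", "structure_id", "structure_name"]


@dataclass
class VolumeImage:
    """A 3D scalar grid with geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensity per voxel (arbitrary units).
    spacing : tuple of float
        Voxel size in mm per axis; the study acquisition was 0.08 mm
        isotropic, the synthetic phantoms default to 0.16 mm.
    origin : tuple of float
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.validate()

    # -- geometry helpers -------------------------------------------------
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.dims[a]) * self.spacing[a]
            for a in range(3)
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def center_world(self) -> np.ndarray:
        """World coordinates of the geometric centre of the grid."""
        return self.index_to_world((np.asarray(self.dims, float) - 1.0) / 2.0)

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D data, got {self.data.ndim}D array of shape {self.data.shape}"
            )
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities contain non-finite values")

    def copy_with(self, data: np.ndarray) -> "VolumeImage":
        return type(self)(data, spacing=self.spacing, origin=self.origin, axcodes=self.axcodes)


@dataclass
class LabelMap(VolumeImage):
    """Integer region assignment per voxel; 0 is background."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label map contains non-integer values")
            self.data = rounded.astype(np.int32)
        super().__post_init__()
        if self.data.min() < 0:
            raise ValueError("label values must be non-negative")

    def label_census(self) -> dict[int, int]:
        """Voxel count per nonzero label."""
        vals, counts = np.unique(self.data, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


@dataclass
class LabelTable:
    """Mapping from atlas labels to merged structures of interest."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in LABEL_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        if df["label_id"].duplicated().any():
            dupes = sorted(df.loc[df["label_id"].duplicated(), "label_id"].tolist())
            raise ValueError(f"duplicate label_id entries: {dupes}")
        if (df["label_id"] <= 0).any():
            raise ValueError("label_id values must be positive (0 is background)")
        if df["structure_id"].isna().any() or (df["structure_id"] <= 0).any():
            raise ValueError("every label must map to a positive structure_id")
        # one name per structure id
        name_per_id = df.groupby("structure_id")["structure_name"].nunique()
        if (name_per_id > 1).any():
            raise ValueError("structure_id mapped to more than one structure_name")

    @property
    def n_labels(self) -> int:
        return len(self.frame)

    @property
    def n_structures(self) -> int:
        return self.frame["structure_id"].nunique()

    @property
    def structure_names(self) -> dict[int, str]:
        return dict(
            self.frame.drop_duplicates("structure_id")
            .set_index("structure_id")["structure_name"]
        )

    def label_to_structure(self) -> dict[int, int]:
        return dict(zip(self.frame["label_id"], self.frame["structure_id"]))


# -- NIfTI I/O ------------------------------------------------------------

def _check_nifti_path(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"expected a NIfTI-1 path (.nii/.nii.gz), got {path!r}")
    return path


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a NIfTI-1 volume, reoriented to canonical RAS axis order.

    Label maps (integer on-disk dtype) come back as :class:`LabelMap`.
    """
    path = _check_nifti_path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"expected 3D image, got {img.ndim}D in {path}")
    img = nib.as_closest_canonical(img)
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    origin = tuple(float(x) for x in affine[:3, 3])
    data = np.asanyarray(img.dataobj)
    cls = LabelMap if np.issubdtype(data.dtype, np.integer) else VolumeImage
    axcodes = tuple(nib.aff2axcodes(affine))
    return cls(data, spacing=spacing, origin=origin, axcodes=axcodes)


def write_volume(img: VolumeImage, path: str | os.PathLike) -> str:
    """Write a volume or label map as NIfTI-1; labels stored as int16/int32."""
    path = _check_nifti_path(path)
    img.validate()
    data = img.data
    if isinstance(img, LabelMap):
        dtype = np.int16 if data.max(initial=0) < 2**15 else np.int32
        data = data.astype(dtype)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(img.spacing) + [1.0])
    affine[:3, 3] = img.origin
    nifti = nib.Nifti1Image(data, affine)
    nifti.header.set_zooms(img.spacing)
    nib.save(nifti, path)
    return path


# -- label tables ---------------------------------------------------------

def read_label_table(path: str | os.PathLike) -> LabelTable:
    """Read a tab-separated label table and validate the label→structure map."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such label table: {path}")
    df = pd.read_csv(path, sep="\t")
    return LabelTable(df)


def write_label_table(table: LabelTable, path: str | os.PathLike) -> str:
    table.frame.to_csv(path, sep="\t", index=False)
    return os.fspath(path)


def load_study_label_table() -> LabelTable:
    """The packaged 39-label → 19-structure merge table.

    The ventricle grouping (cerebral aqueduct, lateral, third and fourth
    ventricles) is fixed by the study design; which of the remaining atlas
    sublabels fold into each structure is not published, so the packaged
    grouping (left/right or subdivision pairs per structure) is an assumption
    documented in the table itself.
    """
    here = os.path.dirname(__file__)
    return read_label_table(os.path.join(here, "data", "label_table_39to19.tsv"))
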