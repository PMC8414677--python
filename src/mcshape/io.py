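"""Reading and writing of binary segmentation masks and cohort manifests.

All masks live on a fixed grid convention: occupancy axis order is
``(slice, row, column)``, 0-based, voxel-center coordinates, with physical
position ``origin + index * spacing`` in millimetres.  NIfTI files store data
in ``(i, j, k)`` order with ``k`` the slice direction, so the loader
transposes once at read time and the writer undoes it; a voxel set at grid
index ``(s, r, c)`` always re-reads at ``(s, r, c)``.

Rotated affines (off-diagonal terms in the voxel-to-world matrix) are
rejected rather than resampled: silent resampling changes shape features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelMask",
    "CohortManifest",
    "MANIFEST_COLUMNS",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "affected_side",
    "nvc_left",
    "nvc_right",
    "mask_left",
    "mask_right",
]

GROUPS = ("PTN", "HC")
SIDES = ("left", "right", "none")
YESNO = ("yes", "no")


@dataclass
class VoxelMask:
    """A binary region of interest on a regular anisotropic grid.

    Parameters
    ----------
    occupancy
        3D boolean array in ``(slice, row, column)`` axis order.
    spacing
        Physical voxel edge lengths in mm, one per axis, strictly positive.
    origin
        Physical coordinate in mm of the center of voxel ``(0, 0, 0)``.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got {occ.ndim}D")
        if occ.dtype != bool:
            values = np.unique(occ)
            if len(values) > 2:
                raise ValueError(
                    "occupancy must be binary; found "
                    f"{len(values)} distinct values"
                )
            occ = occ != 0
        self.occupancy = occ
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")

    @property
    def empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def occupied_coordinates(self) -> np.ndarray:
        """Physical mm coordinates of occupied voxel centers, shape (N, 3)."""
        idx = np.argwhere(self.occupancy)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class CohortManifest:
    """Validated per-subject table: group, affected side, NVC flags, mask paths."""

    table: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
        bad_group = sorted(set(df["group"]) - set(GROUPS))
        if bad_group:
            raise ValueError(f"unknown group tokens: {bad_group} (expected {GROUPS})")
        bad_side = sorted(set(df["affected_side"]) - set(SIDES))
        if bad_side:
            raise ValueError(f"unknown affected_side tokens: {bad_side}")
        for col in ("nvc_left", "nvc_right"):
            bad = sorted(set(df[col]) - set(YESNO))
            if bad:
                raise ValueError(f"unknown {col} tokens: {bad}")
        # HC subjects have no affected side by definition; normalise silently.
        hc = df["group"] == "HC"
        df.loc[hc, "affected_side"] = "none"
        ptn_none = df[(df["group"] == "PTN") & (df["affected_side"] == "none")]
        if len(ptn_none):
            raise ValueError(
                "PTN rows must name an affected side; offending subjects: "
                f"{ptn_none['subject_id'].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_ptn(self) -> int:
        return int((self.table["group"] == "PTN").sum())

    @property
    def n_hc(self) -> int:
        return int((self.table["group"] == "HC").sum())

    def mask_path(self, subject_id: str, side: str) -> Path:
        row = self.table.loc[self.table["subject_id"] == subject_id].iloc[0]
        p = Path(row[f"mask_{side}"])
        return p if p.is_absolute() else self.base_dir / p


def _check_affine(affine: np.ndarray, path) -> np.ndarray:
    """Return per-axis spacing from a diagonal affine; reject rotations."""
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise ValueError(
            f"{path}: affine has off-diagonal (rotated/oblique) terms; "
            "resampling would change shape features, so rotated affines are "
            "rejected — reorient the mask to an axis-aligned grid first"
        )
    zooms = np.abs(np.diag(rot))
    if np.any(zooms <= 0):
        raise ValueError(
            f"{path}: non-positive voxel spacing in NIfTI affine/pixdim: {zooms}"
        )
    return zooms


def read_mask(path) -> VoxelMask:
    """Load a NIfTI-1 binary mask as a :class:`VoxelMask`.

    Any nonzero value counts as occupied (label maps from different exporters
    use different label values).  An all-zero mask is returned flagged empty
    with a warning rather than raising, so batch extraction can skip it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D data array, got shape {data.shape}")
    zooms = _check_affine(img.affine, path)
    # NIfTI stores (i, j, k) with k the slice axis; our grid is (slice, row, column).
    occupancy = np.ascontiguousarray(np.transpose(data != 0, (2, 1, 0)))
    spacing = tuple(float(z) for z in zooms[::-1])
    origin = tuple(float(t) for t in img.affine[:3, 3][::-1])
    mask = VoxelMask(occupancy, spacing, origin)
    if mask.empty:
        warnings.warn(f"{path}: mask contains no occupied voxels", stacklevel=2)
    return mask


def write_mask(mask: VoxelMask, path) -> Path:
    """Write a :class:`VoxelMask` to NIfTI-1 so that re-reading round-trips
    occupancy, spacing and origin bit-exactly."""
    path = Path(path)
    data = np.transpose(mask.occupancy.astype(np.uint8), (2, 1, 0))
    affine = np.diag(list(mask.spacing[::-1]) + [1.0])
    affine[:3, 3] = mask.origin[::-1]
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(mask.spacing[::-1])
    nib.save(img, str(path))
    return path


def read_manifest(path) -> CohortManifest:
    """Read a comma- or tab-delimited cohort manifest with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    manifest = CohortManifest(df, base_dir=path.parent)
    for _, row in manifest.table.iterrows():
        for side in ("left", "right"):
            p = manifest.mask_path(row["subject_id"], side)
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest references missing mask for subject "
                    f"{row['subject_id']} ({side}): {p}"
                )
    return manifest


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
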