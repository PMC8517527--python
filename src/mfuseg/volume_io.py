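"""NIfTI volume I/O and slice/volume reassembly.

Internal convention: grids are indexed (z, y, x) with spacing stored in the
same order, so the slice index is always the leading axis.  NIfTI stores
data (x, y, z); the transpose happens at the I/O boundary and the affine is
carried through untouched — all geometry inside the toolkit is voxel-index
based, with spacing applied only when metrics need physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

VALID_LABELS = frozenset({0, 1, 2})


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components (dz, dy, dx), got {spacing}")
    for s in spacing:
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """3-D scalar intensity grid with per-axis voxel spacing in mm."""

    voxels: np.ndarray                      # (z, y, x)
    spacing: tuple[float, float, float]     # (dz, dy, dx) mm
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.voxels.ndim}-D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def slices(self):
        """Iterate over z-planes (2-D arrays)."""
        for k in range(self.voxels.shape[0]):
            yield self.voxels[k]


@dataclass
class LabelVolume:
    """3-D integer mask: 0 = background, 1 = liver, 2 = tumor."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3-D label volume, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("label volume must contain integers")
            self.labels = self.labels.astype(np.uint8)
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"label volume contains values outside {{0,1,2}}: {sorted(bad)}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def slices(self):
        for k in range(self.labels.shape[0]):
            yield self.labels[k]


def _load(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D image in {path}")
    zooms = img.header.get_zooms()[:3]
    for axis, z in enumerate(zooms):
        if not np.isfinite(z) or z <= 0:
            raise ValueError(f"non-positive spacing in header field pixdim[{axis + 1}] of {path}: {z}")
    # NIfTI (x, y, z) -> internal (z, y, x); zooms reversed to (dz, dy, dx)
    return data.T, tuple(float(z) for z in reversed(zooms)), img.affine


def read_volume(path) -> CTVolume:
    """Read a NIfTI scalar volume as a :class:`CTVolume`."""
    data, spacing, affine = _load(path)
    return CTVolume(voxels=data, spacing=spacing, affine=affine)


def read_labels(path) -> LabelVolume:
    """Read a NIfTI integer mask as a :class:`LabelVolume`."""
    data, spacing, affine = _load(path)
    return LabelVolume(labels=data, spacing=spacing, affine=affine)


def write_volume(vol: CTVolume | LabelVolume, path) -> Path:
    """Write a volume to NIfTI; labels are stored as unsigned 8-bit."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.uint8)
    elif isinstance(vol, CTVolume):
        data = np.asarray(vol.voxels, dtype=np.float32)
    else:
        raise TypeError(f"expected CTVolume or LabelVolume, got {type(vol).__name__}")
    dz, dy, dx = vol.spacing
    affine = vol.affine if vol.affine is not None else np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data.T, affine)  # internal (z,y,x) -> NIfTI (x,y,z)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, str(path))
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc
    return path


def reconstruct_volume(slices: Sequence[np.ndarray], spacing,
                       affine: np.ndarray | None = None) -> LabelVolume:
    """Stack ordered 2-D label planes into a LabelVolume.

    The list order defines the z coordinate: plane ``k`` becomes z-plane
    ``k`` of the output, which inherits ``spacing`` from the source volume.
    """
    if len(slices) == 0:
        raise ValueError("cannot reconstruct a volume from an empty slice list")
    planes = [np.asarray(s) for s in slices]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ValueError(f"slices have mismatched shapes: {sorted(shapes)}")
    if planes[0].ndim != 2:
        raise ValueError(f"slices must be 2-D, got {planes[0].ndim}-D")
    return LabelVolume(labels=np.stack(planes, axis=0), spacing=spacing, affine=affine)
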