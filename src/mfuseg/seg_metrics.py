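"""Volumetric segmentation metrics in physical units.

Six metrics compare a ground-truth mask A against a prediction B:

* boundary-distance based — ASSD (mean), MSSD (maximum, i.e. symmetric
  Hausdorff) and RMSD (root mean square) of the pooled bidirectional
  surface distances.  A surface voxel is a foreground voxel with at least
  one background face-neighbour (6-connectivity, grid border counts as
  background); distances are Euclidean in mm between voxel centres under
  anisotropic spacing, computed with a spacing-aware distance transform.
* size based — RVD, the signed relative volume difference
  ``(|B| - |A|) / |A|`` (positive = over-segmentation).
* overlap based — VOE, ``100 * (1 - Jaccard)`` in percent, and the Dice
  coefficient ``2|A n B| / (|A| + |B|)`` in [0, 1].

Empty-mask conventions: dice(empty, empty) = 1, voe(empty, empty) = 0;
surface-distance metrics and RVD with an empty reference are undefined and
reported as missing (None), never as 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_mask(a, name: str = "mask") -> np.ndarray:
    a = np.asarray(a)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        a = a.astype(bool)
    if a.ndim != 3:
        raise ValueError(f"{name} must be 3-D, got {a.ndim}-D")
    return a


@dataclass
class SurfaceSet:
    """Surface voxel coordinates of a binary mask, with spacing metadata."""

    coords: np.ndarray                      # (K, 3) integer (z, y, x) triples
    spacing: tuple[float, float, float]


@dataclass
class SurfaceDistanceSet:
    """Pooled bidirectional surface distances in mm.

    Contains d(s_A, S(B)) for every surface voxel of A followed by
    d(s_B, S(A)) for every surface voxel of B; N = |S(A)| + |S(B)|.
    """

    distances: np.ndarray

    @property
    def n(self) -> int:
        return int(self.distances.size)


@dataclass
class StructureMetrics:
    """The six metrics for one structure; None marks an undefined value."""

    assd: float | None
    mssd: float | None
    rmsd: float | None
    rvd: float | None
    voe: float
    dice: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetricReport:
    liver: StructureMetrics
    tumor: StructureMetrics

    def to_dict(self) -> dict:
        return {"liver": self.liver.to_dict(), "tumor": self.tumor.to_dict()}


def surface_mask(mask) -> np.ndarray:
    """Boolean mask of surface voxels (foreground with a background
    face-neighbour; voxels on the grid border are surface)."""
    mask = _as_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=FACE_STRUCTURE, border_value=0)
    return mask & ~eroded


def extract_surface(mask, spacing) -> SurfaceSet:
    sm = surface_mask(mask)
    return SurfaceSet(coords=np.argwhere(sm), spacing=tuple(float(s) for s in spacing))


def surface_distances(a, b, spacing) -> SurfaceDistanceSet:
    """Pooled symmetric surface distances between two non-empty masks."""
    a, b = _as_mask(a, "A"), _as_mask(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("undefined surface distance: at least one mask is empty")
    sa, sb = surface_mask(a), surface_mask(b)
    spacing = tuple(float(s) for s in spacing)
    # distance_transform_edt gives, at every voxel, the distance to the
    # nearest zero of its input; feed it the complement of each surface.
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    pooled = np.concatenate([dt_b[sa], dt_a[sb]])
    return SurfaceDistanceSet(distances=pooled)


def _check_nonempty(dset: SurfaceDistanceSet) -> np.ndarray:
    if dset.n == 0:
        raise ValueError("empty surface-distance set")
    return dset.distances


def assd(dset: SurfaceDistanceSet) -> float:
    """Average symmetric surface distance (mm)."""
    return float(_check_nonempty(dset).mean())


def mssd(dset: SurfaceDistanceSet) -> float:
    """Maximum symmetric surface distance / symmetric Hausdorff (mm)."""
    return float(_check_nonempty(dset).max())


def rmsd(dset: SurfaceDistanceSet) -> float:
    """Root-mean-square symmetric surface distance (mm)."""
    d = _check_nonempty(dset)
    return float(np.sqrt(np.mean(d * d)))


def rvd(a, b, signed: bool = True) -> float:
    """Relative volume difference (|B| - |A|) / |A|; dimensionless.

    Signed by default so over- vs under-segmentation is visible; pass
    ``signed=False`` for the absolute variant.
    """
    a, b = _as_mask(a, "A"), _as_mask(b, "B")
    va, vb = int(a.sum()), int(b.sum())
    if va == 0:
        raise ValueError("RVD undefined for an empty reference mask A")
    value = (vb - va) / va
    return float(abs(value) if not signed else value)


def voe(a, b) -> float:
    """Volumetric overlap error in percent: 100 * (1 - |AnB| / |AuB|)."""
    a, b = _as_mask(a, "A"), _as_mask(b, "B")
    union = int((a | b).sum())
    if union == 0:
        raise ValueError("VOE undefined: both masks are empty")
    inter = int((a & b).sum())
    return float(100.0 * (1.0 - inter / union))


def dice(a, b) -> float:
    """Dice similarity coefficient 2|AnB| / (|A| + |B|), in [0, 1]."""
    a, b = _as_mask(a, "A"), _as_mask(b, "B")
    va, vb = int(a.sum()), int(b.sum())
    if va + vb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return float(2.0 * int((a & b).sum()) / (va + vb))


def _structure_metrics(a: np.ndarray, b: np.ndarray, spacing,
                       signed_rvd: bool = True) -> StructureMetrics:
    a_empty, b_empty = not a.any(), not b.any()
    if a_empty and b_empty:
        # absent in both ground truth and prediction: perfect agreement on
        # overlap metrics, distances undefined
        return StructureMetrics(assd=None, mssd=None, rmsd=None, rvd=None, voe=0.0, dice=1.0)
    d = dice(a, b)
    v = voe(a, b)
    r = rvd(a, b, signed=signed_rvd) if not a_empty else None
    if a_empty or b_empty:
        return StructureMetrics(assd=None, mssd=None, rmsd=None, rvd=r, voe=v, dice=d)
    ds = surface_distances(a, b, spacing)
    return StructureMetrics(assd=assd(ds), mssd=mssd(ds), rmsd=rmsd(ds), rvd=r, voe=v, dice=d)


def evaluate_volume(pred, gt, liver_excludes_tumor: bool = False,
                    signed_rvd: bool = True) -> MetricReport:
    """Six-metric report for liver and tumor, ground truth ``gt`` vs
    prediction ``pred``.

    By default the liver structure merges labels {1, 2} (a tumor voxel lies
    inside the liver); ``liver_excludes_tumor=True`` evaluates the strict
    label == 1 region instead.  Spacing is taken from the ground truth.
    """
    pl, gl = np.asarray(pred.labels), np.asarray(gt.labels)
    if pl.shape != gl.shape:
        raise ValueError(f"prediction and ground truth shapes differ: {pl.shape} vs {gl.shape}")
    if not np.allclose(pred.spacing, gt.spacing):
        raise ValueError(f"prediction and ground truth spacings differ: {pred.spacing} vs {gt.spacing}")
    spacing = gt.spacing
    if liver_excludes_tumor:
        liver_a, liver_b = gl == 1, pl == 1
    else:
        liver_a, liver_b = gl >= 1, pl >= 1
    return MetricReport(
        liver=_structure_metrics(liver_a, liver_b, spacing, signed_rvd),
        tumor=_structure_metrics(gl == 2, pl == 2, spacing, signed_rvd),
    )
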