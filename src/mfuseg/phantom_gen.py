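"""Seeded CT-like phantom volumes with liver/tumor labels.

Each phantom is a dark background, one mid-intensity ellipsoidal
liver-like blob (label 1), and 1-3 spherical tumor inclusions strictly
inside the liver (label 2), hypo- or hyper-intense relative to the liver,
plus additive Gaussian noise.  Default intensities are on a Hounsfield-like
scale: background -100 (mixed fat/air/soft tissue outside the liver),
liver 60, tumors offset by +-40 — the contrast regime of portal-venous CT,
not a physical CT simulation.  Geometry lives in voxel index space; the
default grid is deliberately anisotropic (2.5 mm slices, 0.7 mm in-plane)
so the distance metrics are exercised with realistic spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import CTVolume, LabelVolume

_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (16, 64, 64)          # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)  # mm
    liver_radii: tuple[float, float, float] = (6.0, 22.0, 22.0)  # voxels
    liver_intensity: float = 60.0
    center_jitter: float = 2.0          # max |offset| of liver center, voxels
    radii_jitter: float = 0.1           # relative jitter of liver radii
    tumor_count_range: tuple[int, int] = (1, 3)
    tumor_radius_range: tuple[float, float] = (2.0, 4.0)  # voxels
    tumor_intensity_offset: float = 40.0
    tumor_hypo_fraction: float = 0.5    # probability a tumor is darker than liver
    background_intensity: float = -100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if any(s < 8 for s in self.shape):
            raise ValueError(f"every shape component must be >= 8, got {self.shape}")
        if self.tumor_radius_range[1] >= min(self.liver_radii):
            raise ValueError(
                f"largest tumor radius {self.tumor_radius_range[1]} must be strictly "
                f"smaller than the smallest liver radius {min(self.liver_radii)}"
            )
        if not (0 <= self.tumor_hypo_fraction <= 1):
            raise ValueError("tumor_hypo_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom(cfg: PhantomConfig) -> tuple[CTVolume, LabelVolume]:
    """Generate one phantom (image, labels) pair, deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    center = np.array([nz / 2, ny / 2, nx / 2]) + rng.uniform(-cfg.center_jitter, cfg.center_jitter, 3)
    radii = np.array(cfg.liver_radii) * (1.0 + rng.uniform(-cfg.radii_jitter, cfg.radii_jitter, 3))
    liver = _ellipsoid_mask(cfg.shape, center, radii)

    labels = np.zeros(cfg.shape, dtype=np.uint8)
    labels[liver] = 1

    n_tumors = int(rng.integers(cfg.tumor_count_range[0], cfg.tumor_count_range[1] + 1))
    tumor_info = []
    for _ in range(n_tumors):
        r = float(rng.uniform(*cfg.tumor_radius_range))
        hypo = bool(rng.random() < cfg.tumor_hypo_fraction)
        placed = False
        # sample centers inside the per-axis region where a sphere of this
        # radius (plus the one-voxel dilation margin) can still fit
        feasible = np.clip(1.0 - (r + 1.5) / radii, 0.0, None)
        for _attempt in range(_PLACEMENT_RETRIES):
            c = center + rng.uniform(-feasible, feasible) * radii
            sphere = _ellipsoid_mask(cfg.shape, c, (r, r, r))
            if not sphere.any():
                continue
            # strict interiority: the sphere dilated by one voxel must stay
            # inside the liver ellipsoid support
            dilated = ndimage.binary_dilation(sphere, ndimage.generate_binary_structure(3, 1))
            if (dilated & ~liver).any():
                continue
            labels[sphere] = 2
            tumor_info.append({"center": tuple(c), "radius": r, "hypo": hypo})
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a tumor of radius {r:.2f} voxels strictly inside the "
                f"liver after {_PLACEMENT_RETRIES} attempts (constraint: tumor sphere "
                f"dilated by one voxel must remain within the liver ellipsoid)"
            )

    voxels = np.full(cfg.shape, cfg.background_intensity, dtype=np.float64)
    voxels[labels == 1] = cfg.liver_intensity
    # assign tumor intensities sphere by sphere so hypo/hyper mixes are possible
    tumor_mask = labels == 2
    voxels[tumor_mask] = cfg.liver_intensity  # base, overwritten below
    for info in tumor_info:
        sphere = _ellipsoid_mask(cfg.shape, info["center"], (info["radius"],) * 3)
        offset = -cfg.tumor_intensity_offset if info["hypo"] else cfg.tumor_intensity_offset
        voxels[sphere & tumor_mask] = cfg.liver_intensity + offset
    if cfg.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    vol = CTVolume(voxels=voxels, spacing=cfg.spacing)
    lab = LabelVolume(labels=labels, spacing=cfg.spacing)
    return vol, lab


def generate_dataset(n: int, cfg: PhantomConfig, seed: int):
    """Generate ``n`` independent phantoms with per-item derived seeds.

    Returns (pairs, manifest): pairs is a list of (CTVolume, LabelVolume);
    the manifest records each item's seed and parameter draws so any item
    can be regenerated exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    pairs, rows = [], []
    for i, s in enumerate(item_seeds):
        item_cfg = replace(cfg, seed=int(s))
        vol, lab = generate_phantom(item_cfg)
        pairs.append((vol, lab))
        rows.append({
            "item": i,
            "seed": int(s),
            "n_tumors": int(ndimage.label(lab.labels == 2)[1]),
            "tumor_voxels": int((lab.labels == 2).sum()),
            "liver_voxels": int((lab.labels >= 1).sum()),
        })
    manifest = pd.DataFrame(rows)
    return pairs, manifest


def generate_slice_dataset(n_slices: int, cfg: PhantomConfig, seed: int,
                           liver_only: bool = False):
    """Collect (image slice, label slice) pairs from generated phantoms.

    Generates phantoms with per-item seeds until ``n_slices`` z-planes have
    been gathered.  All planes are kept by default so the model also learns
    to stay silent on background-only slices; ``liver_only`` restricts to
    planes containing liver.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_slices:
        item_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
        vol, lab = generate_phantom(item_cfg)
        for img_plane, lab_plane in zip(vol.slices(), lab.slices()):
            if liver_only and not (lab_plane >= 1).any():
                continue
            out.append((img_plane, lab_plane))
            if len(out) == n_slices:
                break
    return out
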