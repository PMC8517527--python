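"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions (exhaustive
scans, all-pairs distances, elementwise loops) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

FACE_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def brute_surface_coords(mask: np.ndarray) -> np.ndarray:
    """Surface voxels by exhaustive 6-neighbour scan; border is background."""
    mask = np.asarray(mask, dtype=bool)
    nz, ny, nx = mask.shape
    out = []
    for z, y, x in np.argwhere(mask):
        for dz, dy, dx in FACE_OFFSETS:
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not mask[zz, yy, xx]:
                out.append((z, y, x))
                break
    return np.array(out, dtype=int).reshape(-1, 3)


def brute_pooled_distances(a: np.ndarray, b: np.ndarray, spacing) -> np.ndarray:
    """Pooled bidirectional min-over-all-pairs surface distances in mm."""
    sa = brute_surface_coords(a) * np.asarray(spacing)
    sb = brute_surface_coords(b) * np.asarray(spacing)
    d = cdist(sa, sb)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


def hounsfield_oracle(plane: np.ndarray) -> np.ndarray:
    """Elementwise re-evaluation of the HU filter from its definition."""
    plane = np.asarray(plane, dtype=float)
    m = plane.min()
    intercept = 0.1 * m if m <= 0 else -m
    out = np.empty_like(plane)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            out[i, j] = 0.00390625 * plane[i, j] + intercept
    return out


def standardize_oracle(plane: np.ndarray, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Elementwise re-evaluation of the standardization transform."""
    plane = np.asarray(plane, dtype=float)
    out = np.empty_like(plane)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            v = plane[i, j]
            out[i, j] = (alpha * v + beta) + (v / 255.0) ** gamma * 255.0
    return out


def conv2d_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                  stride: int, padding: int) -> np.ndarray:
    """Direct quadruple-loop cross-correlation for small inputs."""
    n, cin, h, wi = x.shape
    cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wi + 2 * padding - k) // stride + 1
    y = np.zeros((n, cout, ho, wo))
    for ni in range(n):
        for o in range(cout):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[ni, :, i * stride : i * stride + k, j * stride : j * stride + k]
                    y[ni, o, i, j] = (patch * w[o]).sum()
            if b is not None:
                y[ni, o] += b[o]
    return y


def random_blob(rng: np.random.Generator, shape, n_seeds: int = 3,
                radius_range=(1.5, 4.0)) -> np.ndarray:
    """Union of a few random balls; guaranteed non-empty."""
    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.indices(shape)
    for _ in range(n_seeds):
        c = rng.uniform(0, np.array(shape) - 1)
        r = rng.uniform(*radius_range)
        mask |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r ** 2
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    return mask
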