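"""CT slice preprocessing: Hounsfield-unit filtering and mean-driven
standardization.

The pipeline per slice is

1. ``H(I) = slope * I + Intercept`` with ``slope = 0.00390625`` (= 1/256)
   and ``Intercept = 0.1 * min(I)`` when ``min(I) <= 0``, else ``-min(I)``.
   This collapses the raw HU range into a narrow band centred on
   soft-tissue values and anchors it against per-scanner offsets.
2. Min-max rescale of the filtered slice to the working scale [0, 255]
   (the standardization's gamma term presupposes that domain).
3. Parameter selection from the slice mean mu: dark slices (low mean)
   receive stronger brightness/contrast adjustment.  With
   ``u = clip(1 - mu/mu_ref, 0, 1)`` and ``mu_ref = 128`` (midpoint of the
   working scale) the parameters are ``alpha = 1 + u`` in [1, 2],
   ``beta = 1 + 0.2 u`` in [1, 1.2], ``gamma = 1.5 + 0.5 u`` in [1.5, 2].
4. Standardization ``S(I) = (alpha * I + beta) + (I / 255)^gamma * 255``:
   an affine brightness/scale term plus a gamma contrast term.

Stages compose sequentially (H feeds S); an additive combination of the two
stage outputs is available via ``mode="sum"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_io import CTVolume

HOUNSFIELD_SLOPE = 0.00390625  # 1/256
DEFAULT_MU_REF = 128.0

ALPHA_RANGE = (1.0, 2.0)
BETA_RANGE = (1.0, 1.2)
GAMMA_RANGE = (1.5, 2.0)


@dataclass(frozen=True)
class PreprocessParams:
    """Standardization parameters for one slice.

    alpha/beta scale and shift the intensities, gamma adjusts contrast; mu
    is the slice mean they were derived from (on the [0, 255] scale).
    """

    alpha: float
    beta: float
    gamma: float
    mu: float
    slope: float = HOUNSFIELD_SLOPE

    def __post_init__(self):
        for name, value, (lo, hi) in (
            ("alpha", self.alpha, ALPHA_RANGE),
            ("beta", self.beta, BETA_RANGE),
            ("gamma", self.gamma, GAMMA_RANGE),
        ):
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside its allowed interval [{lo}, {hi}]")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


def _check_finite(plane: np.ndarray, op: str) -> np.ndarray:
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError(f"{op} expects a 2-D slice, got {plane.ndim}-D")
    if not np.isfinite(plane).all():
        raise ValueError(f"{op} requires finite intensities (found NaN/Inf)")
    return plane


def hounsfield_filter(plane: np.ndarray, slope: float = HOUNSFIELD_SLOPE) -> np.ndarray:
    """Apply the HU filter ``slope * I + Intercept`` elementwise.

    The intercept depends on the sign of the slice minimum:
    ``0.1 * min(I)`` when ``min(I) <= 0`` (raw HU slices, air ~ -1000),
    ``-min(I)`` when ``min(I) > 0`` (already-offset intensities).
    """
    plane = _check_finite(plane, "hounsfield_filter")
    m = float(plane.min())
    intercept = 0.1 * m if m <= 0 else -m
    return slope * plane + intercept


def rescale_to_working_range(plane: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255]; a constant plane maps to all zeros."""
    plane = np.asarray(plane, dtype=float)
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.zeros_like(plane)
    return (plane - lo) * (255.0 / (hi - lo))


def select_params(mu: float, mu_ref: float = DEFAULT_MU_REF) -> PreprocessParams:
    """Map a slice mean to (alpha, beta, gamma) by linear interpolation.

    ``mu >= mu_ref`` gives the weakest adjustment (1, 1, 1.5); ``mu = 0``
    the strongest (2, 1.2, 2); the mapping is monotone non-increasing in mu
    and always lands inside the allowed intervals.
    """
    mu = float(mu)
    if not np.isfinite(mu) or mu < 0:
        raise ValueError(f"slice mean must be finite and >= 0 on the [0, 255] scale, got {mu}")
    if mu_ref <= 0:
        raise ValueError(f"mu_ref must be positive, got {mu_ref}")
    u = float(np.clip(1.0 - mu / mu_ref, 0.0, 1.0))
    return PreprocessParams(alpha=1.0 + u, beta=1.0 + 0.2 * u, gamma=1.5 + 0.5 * u, mu=mu)


def standardize(plane: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """Apply ``(alpha * I + beta) + (I / 255)^gamma * 255`` elementwise."""
    plane = _check_finite(plane, "standardize")
    if plane.min() < 0 and not float(params.gamma).is_integer():
        raise ValueError(
            "standardize: negative intensities with fractional gamma would take a "
            "fractional power of a negative number; rescale the slice to [0, 255] first"
        )
    return (params.alpha * plane + params.beta) + (plane / 255.0) ** params.gamma * 255.0


def preprocess_slice(
    plane: np.ndarray,
    mu_ref: float = DEFAULT_MU_REF,
    mu_nonzero: bool = False,
    mode: str = "compose",
    return_params: bool = False,
):
    """Full per-slice pipeline: HU filter -> rescale -> standardize.

    ``mu_nonzero`` computes the slice mean over nonzero pixels only (pixel
    value 0 marks background after rescaling).  ``mode="sum"`` adds the
    HU-filtered plane to the standardized plane instead of composing the
    stages.
    """
    if mode not in ("compose", "sum"):
        raise ValueError(f"mode must be 'compose' or 'sum', got {mode!r}")
    h = hounsfield_filter(plane)
    r = rescale_to_working_range(h)
    if mu_nonzero:
        nz = r[r != 0]
        mu = float(nz.mean()) if nz.size else 0.0
    else:
        mu = float(r.mean())
    params = select_params(mu, mu_ref=mu_ref)
    s = standardize(r, params)
    out = h + s if mode == "sum" else s
    if return_params:
        return out, params
    return out


def preprocess_volume(vol: CTVolume, mu_ref: float = DEFAULT_MU_REF,
                      mu_nonzero: bool = False, mode: str = "compose") -> CTVolume:
    """Apply :func:`preprocess_slice` independently to every z-plane."""
    planes = [preprocess_slice(p, mu_ref=mu_ref, mu_nonzero=mu_nonzero, mode=mode)
              for p in vol.slices()]
    return CTVolume(voxels=np.stack(planes, axis=0), spacing=vol.spacing, affine=vol.affine)


def preprocess_volume_with_params(vol: CTVolume, mu_ref: float = DEFAULT_MU_REF,
                                  mu_nonzero: bool = False, mode: str = "compose"):
    """Like :func:`preprocess_volume` but also returns per-slice parameters."""
    planes, params = [], []
    for p in vol.slices():
        out, pp = preprocess_slice(p, mu_ref=mu_ref, mu_nonzero=mu_nonzero,
                                   mode=mode, return_params=True)
        planes.append(out)
        params.append(pp)
    out_vol = CTVolume(voxels=np.stack(planes, axis=0), spacing=vol.spacing, affine=vol.affine)
    return out_vol, params
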