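"""Image-quality assessment for compressed endoscopic recordings.

Full-reference metrics compare a lossy-decoded frame against its lossless
reference:

* ``mse``  — mean squared error, MSE = (1/mn) Σ (I − K)²
* ``psnr`` — 10·log10(max(I)² / MSE) in decibels; identical images hit
  MSE = 0 and return a documented +inf sentinel
* ``ssim`` — the structural similarity index, the mean over local windows
  of l^α · c^β · s^γ with the standard stabilized luminance, contrast and
  structure comparison terms

``dynamic_range`` is the normalized absolute min–max spread of a single
frame, and NIQE ("natural image quality evaluator") is a completely blind
no-reference score: the distance between an image's MSCN-based
natural-scene-statistics features and a multivariate-Gaussian model of a
pristine corpus — lower is better.  Because the pristine corpus here is the
tier-2 phantom rather than a natural-image collection, absolute NIQE values
are corpus-specific; only orderings (more degradation → higher score) are
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.special import gamma as _gamma

from .errors import DimensionError, EstimationError

__all__ = [
    "SSIMParams",
    "NiqeModel",
    "dynamic_range",
    "mse",
    "psnr",
    "ssim",
    "fit_niqe_model",
    "niqe_score",
    "default_niqe_model",
]


def _as_float(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim == 3 and a.shape[-1] == 3:
        # Rec.601 luma, matching the segmentation-side grayscale convention.
        a = a @ np.array([0.299, 0.587, 0.114])
    if a.ndim != 2:
        raise DimensionError(f"expected a 2-D image (or H,W,3 color), got {a.shape}")
    return a.astype(np.float64)


def dynamic_range(img, bit_depth_max: float = 255.0) -> float:
    """Normalized absolute difference of the min and max pixel value.

    0 means no dynamic range (constant image), 1 means full range.
    """
    a = np.asarray(img, dtype=np.float64)
    return float((a.max() - a.min()) / bit_depth_max)


def mse(I, K) -> float:
    """Mean squared error between two equally shaped images."""
    a, b = np.asarray(I, dtype=np.float64), np.asarray(K, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(I, K, bit_depth_max: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    err = mse(I, K)
    if err == 0.0:
        return math.inf
    return float(10.0 * math.log10(bit_depth_max**2 / err))


@dataclass(frozen=True)
class SSIMParams:
    """Weights and window of the structural-similarity index.

    Defaults: unit exponents, a 7x7 uniform window and the conventional
    stabilization fractions k1 = 0.01, k2 = 0.03 on the 8-bit range.  An
    11x11 Gaussian window (sigma 1.5) is available via ``gaussian=True``.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    gaussian: bool = False
    sigma: float = 1.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must be > 0")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")


def _signed_pow(x: np.ndarray, p: float) -> np.ndarray:
    # Structure term can be negative; exponentiate magnitude, keep sign.
    if p == 1.0:
        return x
    return np.sign(x) * np.abs(x) ** p


def ssim(
    I, K, params: SSIMParams | None = None, bit_depth_max: float = 255.0
) -> float:
    """Mean structural similarity between two equally shaped images.

    Symmetric in its arguments and exactly 1 iff the images are identical.
    Raises :class:`DimensionError` when an image is smaller than the window.
    """
    p = params or SSIMParams()
    a, b = _as_float(I), _as_float(K)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < p.window:
        raise DimensionError(
            f"image {a.shape} smaller than the {p.window}x{p.window} window"
        )
    if np.array_equal(a, b):
        return 1.0  # exact by definition; avoids ~1e-15 filter round-off
    if p.gaussian:
        def filt(x):
            return gaussian_filter(x, sigma=p.sigma, truncate=(p.window // 2) / p.sigma)
        npix = None
    else:
        def filt(x):
            return uniform_filter(x, size=p.window)
        npix = p.window**2

    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    # Unbiased (sample) covariance normalization for the uniform window,
    # matching common reference implementations.
    norm = npix / (npix - 1.0) if npix else 1.0
    va = norm * (uaa - ua * ua)
    vb = norm * (ubb - ub * ub)
    vab = norm * (uab - ua * ub)
    va, vb = np.maximum(va, 0.0), np.maximum(vb, 0.0)

    C1 = (p.k1 * bit_depth_max) ** 2
    C2 = (p.k2 * bit_depth_max) ** 2
    C3 = C2 / 2.0
    sa, sb = np.sqrt(va), np.sqrt(vb)
    lum = (2 * ua * ub + C1) / (ua**2 + ub**2 + C1)
    con = (2 * sa * sb + C2) / (va + vb + C2)
    struc = (vab + C3) / (sa * sb + C3)
    smap = (
        _signed_pow(lum, p.alpha)
        * _signed_pow(con, p.beta)
        * _signed_pow(struc, p.gamma)
    )
    pad = p.window // 2  # crop to windows fully inside the image
    smap = smap[pad : smap.shape[0] - pad, pad : smap.shape[1] - pad]
    return float(smap.mean())


# ---------------------------------------------------------------------------
# NIQE: MSCN coefficients -> GGD/AGGD feature statistics -> Mahalanobis
# distance to a pristine-corpus Gaussian model.
# ---------------------------------------------------------------------------

_GAM_GRID = np.arange(0.2, 10.0, 0.001)
_GGD_RATIO = (_gamma(1.0 / _GAM_GRID) * _gamma(3.0 / _GAM_GRID)) / (
    _gamma(2.0 / _GAM_GRID) ** 2
)


def _ggd_fit(x: np.ndarray) -> tuple[float, float]:
    """Moment-matching fit of a zero-mean generalized Gaussian.

    Returns (shape, variance)."""
    x = x.ravel()
    sigma_sq = float(np.mean(x**2))
    E_abs = float(np.mean(np.abs(x))) + 1e-12
    rho = sigma_sq / (E_abs**2)
    idx = int(np.argmin(np.abs(_GGD_RATIO - rho)))
    return float(_GAM_GRID[idx]), sigma_sq


def _aggd_fit(x: np.ndarray) -> tuple[float, float, float, float]:
    """Fit an asymmetric generalized Gaussian; returns
    (shape, mean, left variance, right variance)."""
    x = x.ravel()
    left = x[x < 0]
    right = x[x >= 0]
    sigma_l = math.sqrt(float(np.mean(left**2))) if left.size else 1e-12
    sigma_r = math.sqrt(float(np.mean(right**2))) if right.size else 1e-12
    gamma_hat = sigma_l / (sigma_r + 1e-12)
    E_abs = float(np.mean(np.abs(x))) + 1e-12
    r_hat = E_abs**2 / (float(np.mean(x**2)) + 1e-12)
    R_hat = r_hat * (gamma_hat**3 + 1) * (gamma_hat + 1) / ((gamma_hat**2 + 1) ** 2)
    ratio = (_gamma(2.0 / _GAM_GRID) ** 2) / (
        _gamma(1.0 / _GAM_GRID) * _gamma(3.0 / _GAM_GRID)
    )
    idx = int(np.argmin(np.abs(ratio - R_hat)))
    alpha = float(_GAM_GRID[idx])
    const = _gamma(2.0 / alpha) / _gamma(1.0 / alpha)
    mean = (sigma_r - sigma_l) * const
    return alpha, float(mean), sigma_l**2, sigma_r**2


def _mscn(img: np.ndarray, sigma: float = 7.0 / 6.0):
    """Mean-subtracted contrast-normalized coefficients and the local sigma."""
    mu = gaussian_filter(img, sigma, truncate=3.0)
    var = gaussian_filter(img * img, sigma, truncate=3.0) - mu * mu
    sd = np.sqrt(np.maximum(var, 0.0))
    return (img - mu) / (sd + 1.0), sd


def _patch_features(patch: np.ndarray) -> np.ndarray:
    """18 features: GGD of the MSCN field + AGGD of 4 pairwise products."""
    feats = list(_ggd_fit(patch))
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]  # H, V, D1, D2 neighbors
    for dy, dx in shifts:
        rolled = np.roll(np.roll(patch, dy, axis=0), dx, axis=1)
        feats.extend(_aggd_fit(patch * rolled))
    return np.asarray(feats, dtype=np.float64)


def _image_features(
    gray: np.ndarray, patch_size: int, sharpness_fraction: float | None
) -> np.ndarray:
    """Per-patch 36-dim features over two scales; patches align spatially.

    ``sharpness_fraction`` keeps only patches whose mean local contrast is
    at least that fraction of the sharpest patch (used during model
    fitting); ``None`` keeps all patches (used at scoring time).
    """
    H, W = gray.shape
    if H < patch_size * 2 or W < patch_size * 2:
        raise DimensionError(
            f"image {gray.shape} too small for patch size {patch_size} over 2 scales"
        )
    mscn1, sd1 = _mscn(gray)
    half = gray.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))
    mscn2, _ = _mscn(half)

    ny, nx = H // patch_size, W // patch_size
    ps2 = patch_size // 2
    sharp = np.empty((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            sharp[iy, ix] = sd1[
                iy * patch_size : (iy + 1) * patch_size,
                ix * patch_size : (ix + 1) * patch_size,
            ].mean()
    if sharpness_fraction is not None:
        keep = sharp >= sharpness_fraction * sharp.max()
    else:
        keep = np.ones((ny, nx), dtype=bool)

    rows = []
    for iy in range(ny):
        for ix in range(nx):
            if not keep[iy, ix]:
                continue
            p1 = mscn1[
                iy * patch_size : (iy + 1) * patch_size,
                ix * patch_size : (ix + 1) * patch_size,
            ]
            p2 = mscn2[iy * ps2 : (iy + 1) * ps2, ix * ps2 : (ix + 1) * ps2]
            rows.append(np.concatenate([_patch_features(p1), _patch_features(p2)]))
    return np.asarray(rows)


@dataclass
class NiqeModel:
    """Multivariate-Gaussian model of pristine-corpus patch features."""

    mean: np.ndarray  # (36,)
    cov: np.ndarray  # (36, 36), symmetric PSD
    patch_size: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape inconsistent with mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


def fit_niqe_model(
    pristine: list[np.ndarray],
    patch_size: int = 32,
    sharpness_fraction: float = 0.75,
) -> NiqeModel:
    """Fit the pristine feature model from a corpus of clean images.

    Requires at least 10x the feature dimension (360) selected patches for
    a stable covariance; raises :class:`EstimationError` otherwise.
    Deterministic given the input order.
    """
    all_rows = []
    for img in pristine:
        gray = _as_float(img)
        all_rows.append(_image_features(gray, patch_size, sharpness_fraction))
    feats = np.vstack([r for r in all_rows if r.size]) if all_rows else np.empty((0, 36))
    dim = 36
    if feats.shape[0] < 10 * dim:
        raise EstimationError(
            f"need >= {10 * dim} pristine patches to fit the model, "
            f"got {feats.shape[0]}"
        )
    mean = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)
    return NiqeModel(mean=mean, cov=cov, patch_size=patch_size)


def niqe_score(img, model: NiqeModel) -> float:
    """Blind quality score: Mahalanobis-type distance of the image's
    feature statistics from the pristine model.  Lower is better; 0 is the
    floor.  Deterministic."""
    gray = _as_float(img)
    feats = _image_features(gray, model.patch_size, sharpness_fraction=None)
    mu = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False) if feats.shape[0] > 1 else np.zeros_like(model.cov)
    pooled = (model.cov + cov) / 2.0
    diff = model.mean - mu
    sol = np.linalg.pinv(pooled, hermitian=True) @ diff
    return float(math.sqrt(max(0.0, float(diff @ sol))))


@lru_cache(maxsize=4)
def default_niqe_model(seed: int = 0, n_frames: int = 120) -> NiqeModel:
    """Pristine model fitted on clean tier-2 phantom frames.

    Built deterministically at first use from the given seed.  Absolute
    scores from this model are corpus-specific; use it for orderings.
    """
    from .phantom import PhantomSpec, generate_recording

    spec = PhantomSpec(T=n_frames, tier=2, noise_sigma=0.0, seed=seed)
    pr = generate_recording(spec)
    frames = [pr.rec.frames[t] for t in range(pr.rec.n_frames)]
    return fit_niqe_model(frames, patch_size=32, sharpness_fraction=0.5)
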