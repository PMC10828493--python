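"""Full-reference image quality metrics with ROI support.

Five scalar scores are implemented for real-valued grayscale images on
[0, 255]:

MSE     mean squared error, (1/wh) * sum (M - N)^2.
PSNR    10 * log10((2^n - 1)^2 / MSE) with n = 8 bits by default.
SSIM    structural similarity computed from *global* image statistics
        (means, variances, covariance of the whole image), i.e. the
        single-window form
        ((2 mu_x mu_y + c1)(2 sigma_xy + c2)) /
        ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))
        with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, L = 255.
        The sliding-window SSIM common elsewhere is deliberately out of
        scope here.
ENL     equivalent number of looks, mean over ROIs of mu^2 / (sigma^2 + eps)
        with population variance and eps = 1e-12 so constant ROIs saturate
        instead of failing.  Higher means smoother homogeneous regions.
ENL uses three ROIs by default; EPI uses boundary-adjacent ROIs.
EPI     edge preservation index: the ratio of summed absolute horizontal
        central differences |I(x+1, y) - I(x-1, y)| of the *noisy* image to
        the same sum on the denoised image, restricted to ROIs near the
        image boundary.  With this orientation stronger smoothing pushes the
        value above 1; no inversion is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, DimensionError

__all__ = [
    "ROISet",
    "SSIMConstants",
    "MetricsReport",
    "default_enl_rois",
    "default_epi_rois",
    "mse",
    "psnr",
    "ssim",
    "enl",
    "epi",
    "evaluate_all",
]

_ENL_EPSILON = 1e-12

Rect = Tuple[int, int, int, int]  # (row0, col0, row1, col1), 0-based, half-open


@dataclass(frozen=True)
class ROISet:
    """A list of rectangular regions of interest (half-open, 0-based)."""

    rois: Tuple[Rect, ...]

    def __post_init__(self) -> None:
        rois = tuple(tuple(int(v) for v in r) for r in self.rois)
        object.__setattr__(self, "rois", rois)
        if not rois:
            raise ConfigurationError("ROISet needs at least one rectangle")
        for r in rois:
            if len(r) != 4:
                raise ConfigurationError(f"ROI must have 4 entries, got {r}")
            r0, c0, r1, c1 = r
            if r1 <= r0 or c1 <= c0 or r0 < 0 or c0 < 0:
                raise ConfigurationError(f"ROI {r} is empty or negative")

    def validate_against(self, shape: Tuple[int, int]) -> None:
        h, w = shape
        for r0, c0, r1, c1 in self.rois:
            if r1 > h or c1 > w:
                raise ConfigurationError(f"ROI {(r0, c0, r1, c1)} exceeds image shape {shape}")

    def extract(self, img: np.ndarray):
        self.validate_against(img.shape)
        return [img[r0:r1, c0:c1] for r0, c0, r1, c1 in self.rois]


@dataclass(frozen=True)
class SSIMConstants:
    """Stability constants of the similarity index."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


@dataclass
class MetricsReport:
    """The five scores for one (reference, noisy, denoised) triple."""

    mse: float
    psnr: float
    ssim: float
    enl: float
    epi: float

    def to_dict(self) -> dict:
        return {"mse": self.mse, "psnr": self.psnr, "ssim": self.ssim,
                "enl": self.enl, "epi": self.epi}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def default_enl_rois(shape: Tuple[int, int], roi_size: int = 32) -> ROISet:
    """Three square ROIs at relative positions (1/4,1/4), (1/4,3/4), (3/4,1/2)."""
    h, w = shape
    s = min(roi_size, h // 2, w // 2)
    half = s // 2

    def square(fr: float, fc: float) -> Rect:
        r0 = min(max(int(round(fr * h)) - half, 0), h - s)
        c0 = min(max(int(round(fc * w)) - half, 0), w - s)
        return (r0, c0, r0 + s, c0 + s)

    return ROISet((square(0.25, 0.25), square(0.25, 0.75), square(0.75, 0.5)))


def default_epi_rois(shape: Tuple[int, int], width: int = 16, inset: int = 1) -> ROISet:
    """Four frames along the borders, inset so the central difference exists."""
    h, w = shape
    width = min(width, max((h - 2 * inset) // 2, 1), max((w - 2 * inset) // 2, 1))
    top = (inset, inset, inset + width, w - inset)
    bottom = (h - inset - width, inset, h - inset, w - inset)
    left = (inset, inset, h - inset, inset + width)
    right = (inset, w - inset - width, h - inset, w - inset)
    return ROISet((top, bottom, left, right))


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(ref: np.ndarray, img: np.ndarray) -> float:
    ref, img = _check_same_shape(ref, img)
    return float(np.mean((ref - img) ** 2))


def psnr(ref: np.ndarray, img: np.ndarray, n_bits: int = 8,
         inf_sentinel: float = math.inf) -> float:
    """Peak signal-to-noise ratio in dB; ``inf_sentinel`` returned at MSE 0."""
    err = mse(ref, img)
    peak = (2.0**n_bits - 1.0) ** 2
    if err == 0.0:
        return inf_sentinel
    return float(10.0 * math.log10(peak / err))


def ssim(ref: np.ndarray, img: np.ndarray, c: SSIMConstants | None = None) -> float:
    ref, img = _check_same_shape(ref, img)
    if c is None:
        c = SSIMConstants()
    mu_x = ref.mean()
    mu_y = img.mean()
    var_x = ref.var()
    var_y = img.var()
    cov = ((ref - mu_x) * (img - mu_y)).mean()
    num = (2.0 * mu_x * mu_y + c.c1) * (2.0 * cov + c.c2)
    den = (mu_x**2 + mu_y**2 + c.c1) * (var_x + var_y + c.c2)
    return float(num / den)


def enl(img: np.ndarray, rois: ROISet | None = None) -> float:
    """Mean over ROIs of mu^2 / (population variance + 1e-12)."""
    img = np.asarray(img, dtype=float)
    if rois is None:
        rois = default_enl_rois(img.shape)
    vals = []
    for patch in rois.extract(img):
        mu = patch.mean()
        var = patch.var()
        vals.append(mu * mu / (var + _ENL_EPSILON))
    return float(np.mean(vals))


def _abs_horizontal_gradient(img: np.ndarray) -> np.ndarray:
    """|I(x+1, y) - I(x-1, y)| with x the column index; border columns give 0."""
    g = np.zeros_like(img)
    g[:, 1:-1] = np.abs(img[:, 2:] - img[:, :-2])
    return g


def epi(noisy: np.ndarray, denoised: np.ndarray, rois: ROISet | None = None) -> float:
    noisy, denoised = _check_same_shape(noisy, denoised)
    if rois is None:
        rois = default_epi_rois(noisy.shape)
    gn = _abs_horizontal_gradient(noisy)
    gd = _abs_horizontal_gradient(denoised)
    num = sum(float(p.sum()) for p in rois.extract(gn))
    den = sum(float(p.sum()) for p in rois.extract(gd))
    if den == 0.0:
        raise DegenerateInputError("denoised image has zero gradient sum on the EPI ROIs")
    return num / den


def evaluate_all(
    ref: np.ndarray,
    noisy: np.ndarray,
    denoised: np.ndarray,
    enl_rois: ROISet | None = None,
    epi_rois: ROISet | None = None,
    c: SSIMConstants | None = None,
) -> MetricsReport:
    """MSE/PSNR/SSIM between reference and denoised; ENL on denoised;
    EPI between noisy and denoised."""
    ref, denoised = _check_same_shape(ref, denoised)
    return MetricsReport(
        mse=mse(ref, denoised),
        psnr=psnr(ref, denoised),
        ssim=ssim(ref, denoised, c),
        enl=enl(denoised, enl_rois),
        epi=epi(noisy, denoised, epi_rois),
    )
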