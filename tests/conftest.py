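"""Shared fixtures and brute-force oracles.

The oracle helpers here are deliberately naive (double loops, explicit
sorting, Fraction arithmetic) so they stay independent of the vectorized
implementations they check.
"""

from fractions import Fraction

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240130)


@pytest.fixture
def random_images(rng):
    """Fifty random 8x8 float images in [0, 255]."""
    return [rng.uniform(0.0, 255.0, (8, 8)) for _ in range(50)]


# --------------------------------------------------------------------------
# oracles

def exact_tent_orbit(x0: Fraction, n: int) -> list:
    """Exact rational-arithmetic tent orbit at mu = 2."""
    xs = [x0]
    for _ in range(n - 1):
        x = xs[-1]
        xs.append(2 * x if x <= Fraction(1, 2) else 2 * (1 - x))
    return xs


def pad_sym(img: np.ndarray, r: int) -> np.ndarray:
    return np.pad(img, r, mode="symmetric")


def brute_correlate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Double-loop correlation with symmetric (reflect) padding."""
    r = kernel.shape[0] // 2
    p = pad_sym(img, r)
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for s in range(-r, r + 1):
                for t in range(-r, r + 1):
                    acc += kernel[s + r, t + r] * p[i + s + r, j + t + r]
            out[i, j] = acc
    return out


def brute_median(img: np.ndarray, ksize: int) -> np.ndarray:
    """Sort-and-pick median with symmetric padding."""
    r = ksize // 2
    p = pad_sym(img, r)
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            window = sorted(
                p[i + s + r, j + t + r]
                for s in range(-r, r + 1)
                for t in range(-r, r + 1)
            )
            out[i, j] = window[len(window) // 2]
    return out


def brute_bilateral(img: np.ndarray, ksize: int, sigma_r: float, sigma_d: float) -> np.ndarray:
    """Double-loop evaluation of the product-of-Gaussians weight formula."""
    import math

    r = ksize // 2
    p = pad_sym(img, r)
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for s in range(-r, r + 1):
                for t in range(-r, r + 1):
                    val = p[i + s + r, j + t + r]
                    wgt = math.exp(
                        -(s * s + t * t) / (2.0 * sigma_d**2)
                        - (img[i, j] - val) ** 2 / (2.0 * sigma_r**2)
                    )
                    num += wgt * val
                    den += wgt
            out[i, j] = num / den
    return out


def brute_mse(a: np.ndarray, b: np.ndarray) -> float:
    h, w = a.shape
    acc = 0.0
    for i in range(h):
        for j in range(w):
            acc += (a[i, j] - b[i, j]) ** 2
    return acc / (h * w)


def brute_ssim(a: np.ndarray, b: np.ndarray, k1=0.01, k2=0.03, L=255.0) -> float:
    n = a.size
    mx = float(a.sum()) / n
    my = float(b.sum()) / n
    vx = float(((a - mx) ** 2).sum()) / n
    vy = float(((b - my) ** 2).sum()) / n
    cov = float(((a - mx) * (b - my)).sum()) / n
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def brute_epi(noisy: np.ndarray, denoised: np.ndarray, rects) -> float:
    def grad_sum(img):
        acc = 0.0
        h, w = img.shape
        for r0, c0, r1, c1 in rects:
            for i in range(r0, r1):
                for j in range(c0, c1):
                    if 1 <= j <= w - 2:
                        acc += abs(img[i, j + 1] - img[i, j - 1])
        return acc

    return grad_sum(noisy) / grad_sum(denoised)
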