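"""Differentiable structural similarity (Wang SSIM) for training losses.

Forward pass matches ``skimage.metrics.structural_similarity`` with
``gaussian_weights=True, sigma=1.5, use_sample_covariance=False`` (11-tap
Gaussian window, K1=0.01, K2=0.03): local statistics are Gaussian-filtered
moments and the mean is taken over the border-cropped SSIM map, so the
retained values never touch the padding and any boundary mode gives the
same number.  The backward pass propagates through the filtered moments
analytically; the Gaussian correlation with zero padding is self-adjoint,
which keeps the adjoint a plain re-application of the same filter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["ssim_value", "ssim_value_and_grad", "SIGMA", "TRUNCATE", "K1", "K2"]

SIGMA = 1.5
TRUNCATE = 3.5  # radius 5 -> 11-tap window, as in the reference SSIM
K1 = 0.01
K2 = 0.03
_PAD = int(TRUNCATE * SIGMA + 0.5)  # border crop, matches the window radius


def _filt(a: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(
        a, sigma=SIGMA, truncate=TRUNCATE, mode="constant", cval=0.0
    )


def _crop_mean_weights(shape: tuple[int, ...]) -> np.ndarray:
    w = np.zeros(shape)
    inner = tuple(slice(_PAD, n - _PAD) for n in shape)
    n_inner = int(np.prod([max(n - 2 * _PAD, 0) for n in shape]))
    if n_inner == 0:
        raise ValueError(f"image {shape} smaller than the SSIM window margin")
    w[inner] = 1.0 / n_inner
    return w


def _ssim_terms(x: np.ndarray, y: np.ndarray, data_range: float):
    c1 = (K1 * data_range) ** 2
    c2 = (K2 * data_range) ** 2
    ux, uy = _filt(x), _filt(y)
    fxx, fyy, fxy = _filt(x * x), _filt(y * y), _filt(x * y)
    vx = fxx - ux * ux
    vy = fyy - uy * uy
    cov = fxy - ux * uy
    a1 = 2 * ux * uy + c1
    a2 = 2 * cov + c2
    b1 = ux * ux + uy * uy + c1
    b2 = vx + vy + c2
    s = (a1 * a2) / (b1 * b2)
    return s, (ux, uy, a1, a2, b1, b2)


def ssim_value(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Mean SSIM of ``y`` against reference ``x`` over the cropped map."""
    s, _ = _ssim_terms(np.asarray(x, float), np.asarray(y, float), data_range)
    w = _crop_mean_weights(s.shape)
    return float((s * w).sum())


def ssim_value_and_grad(
    x: np.ndarray, y: np.ndarray, data_range: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean SSIM and its gradient with respect to ``y`` (reference ``x`` fixed)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s, (ux, uy, a1, a2, b1, b2) = _ssim_terms(x, y, data_range)
    w = _crop_mean_weights(s.shape)
    val = float((s * w).sum())

    inv_bb = 1.0 / (b1 * b2)
    # partials of S with respect to the filtered moments of y
    g_uy = 2 * ux * a2 * inv_bb - 2 * uy * s / b1 - 2 * ux * a1 * inv_bb + 2 * uy * s / b2
    g_fyy = -s / b2  # via vy
    g_fxy = 2 * a1 * inv_bb  # via cov
    # adjoint of the (symmetric, zero-padded) Gaussian filter is the filter
    grad = _filt(w * g_uy) + 2 * y * _filt(w * g_fyy) + x * _filt(w * g_fxy)
    return val, grad
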