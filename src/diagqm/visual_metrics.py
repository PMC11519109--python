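"""Conventional image-quality metrics (ImagQMs): SSIM and PSNR.

SSIM uses the Wang reference settings — 11-tap Gaussian window (sigma 1.5),
K1 = 0.01, K2 = 0.03, population covariances — with the stabilising
constants tied to the *reference* image's data range.  3D volumes are
scored as the mean over 2D slices; the settings used are recorded in every
result so scores remain auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy import stats as sps
from skimage.metrics import structural_similarity

from .volume import ImageVolume

__all__ = ["SsimSettings", "ImagQMResult", "ssim", "psnr", "compare_ssim_paired"]


@dataclass(frozen=True)
class SsimSettings:
    """SSIM window/constant settings (Wang reference defaults)."""

    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03

    @property
    def win_size(self) -> int:
        return 2 * int(3.5 * self.sigma + 0.5) + 1


@dataclass(frozen=True)
class ImagQMResult:
    """SSIM/PSNR of one (reference, test) volume pair."""

    ssim: float
    psnr: float
    per_slice_ssim: tuple[float, ...] = ()
    settings: SsimSettings = field(default_factory=SsimSettings)


def _check_grids(reference: ImageVolume, test: ImageVolume) -> None:
    if reference.shape != test.shape:
        raise ValueError(
            f"grids differ: reference {reference.shape} vs test {test.shape}"
        )


def _slice_ssims(
    reference: ImageVolume, test: ImageVolume, settings: SsimSettings
) -> np.ndarray:
    data_range = float(reference.data.max() - reference.data.min())
    if data_range == 0:
        raise ValueError("reference volume is constant (zero data range)")
    vals = [
        structural_similarity(
            reference.data[:, :, k],
            test.data[:, :, k],
            data_range=data_range,
            gaussian_weights=True,
            sigma=settings.sigma,
            use_sample_covariance=False,
            K1=settings.k1,
            K2=settings.k2,
        )
        for k in range(reference.shape[2])
    ]
    return np.asarray(vals)


def ssim(
    reference: ImageVolume, test: ImageVolume, settings: SsimSettings = SsimSettings()
) -> float:
    """Mean structural similarity of ``test`` against ``reference``.

    Equals 1 exactly iff the images are identical; the data range for the
    stabilising constants is taken from the reference image.
    """
    _check_grids(reference, test)
    return float(_slice_ssims(reference, test, settings).mean())


def psnr(reference: ImageVolume, test: ImageVolume) -> float:
    """Peak signal-to-noise ratio 10*log10(range^2 / MSE) in dB.

    Identical images return ``inf`` (documented sentinel).  The peak range
    is the reference's max - min.
    """
    _check_grids(reference, test)
    mse = float(np.mean((reference.data - test.data) ** 2))
    if mse == 0:
        return float("inf")
    rng = float(reference.data.max() - reference.data.min())
    return float(10.0 * np.log10(rng**2 / mse))


def imagqm(
    reference: ImageVolume, test: ImageVolume, settings: SsimSettings = SsimSettings()
) -> ImagQMResult:
    """Both ImagQMs with per-slice SSIM values and the settings record."""
    _check_grids(reference, test)
    per_slice = _slice_ssims(reference, test, settings)
    return ImagQMResult(
        ssim=float(per_slice.mean()),
        psnr=psnr(reference, test),
        per_slice_ssim=tuple(float(v) for v in per_slice),
        settings=settings,
    )


@dataclass(frozen=True)
class PairedComparison:
    """Paired per-patient metric comparison with a Wilcoxon signed-rank p."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    n: int
    n_zero_dropped: int


def _exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p via the sign-flip null distribution.

    Handles tied absolute differences through midranks: the distribution of
    the positive-rank sum over all 2^n sign assignments is built by dynamic
    programming over doubled (hence integer) midranks, and the two-sided p
    is the probability of a lesser-rank-sum at least as extreme as
    observed.
    """
    ranks = np.rint(2.0 * sps.rankdata(np.abs(diffs))).astype(int)  # doubled midranks
    w_pos = int(ranks[diffs > 0].sum())
    total = int(ranks.sum())
    observed_min = min(w_pos, total - w_pos)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    support = np.arange(total + 1)
    extreme = np.minimum(support, total - support) <= observed_min
    return float(dist[extreme].sum())


def compare_ssim_paired(
    values_a: Sequence[float], values_b: Sequence[float]
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-patient values.

    Zero differences are dropped; the exact sign-flip null distribution
    (tie-capable, via midranks) is used up to n = 25 non-zero differences,
    the tie-corrected normal approximation above.  All differences zero
    gives p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value vectors must be 1D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return PairedComparison(
            float(a.mean()), float(a.std()), float(b.mean()), float(b.std()),
            1.0, a.size, a.size,
        )
    if nonzero.size <= 25:
        p_value = _exact_signed_rank_p(nonzero)
    else:
        res = sps.wilcoxon(a, b, zero_method="wilcox", method="approx", correction=False)
        p_value = float(res.pvalue)
    return PairedComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std()),
        mean_b=float(b.mean()),
        sd_b=float(b.std()),
        p_value=float(p_value),
        n=int(a.size),
        n_zero_dropped=int(a.size - nonzero.size),
    )
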