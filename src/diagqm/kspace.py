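"""Retrospective k-space undersampling of magnitude images.

Accelerated MRI acquires fewer phase-encoding lines.  This module simulates
that retrospectively: a binary line mask keeps a contiguous central band of
low spatial frequencies (20% of the sample budget by default) and draws the
remaining lines from the periphery with a probability that decays
exponentially with distance from the k-space centre.  Applying the mask to
the FFT of each slice and inverting yields the "naive" (zero-filled IFFT)
reconstruction, with the aliasing/blur artefacts of an accelerated scan.

Conventions
-----------
Line indices live in the *centred* (fftshifted) frequency frame: for
``n_lines`` lines the DC line sits at index ``n_lines // 2``.  The mask is
1D over the phase-encoding axis of each 2D slice and is broadcast across the
frequency-encoding axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume

__all__ = [
    "MaskConfig",
    "KSpaceMask",
    "make_undersampling_mask",
    "pad_mask_for_zero_fill",
    "undersample_volume",
]


def _round_half_away(x: float) -> int:
    """Round half away from zero (documented tie-break for line budgets)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x != 0 else 0


@dataclass(frozen=True)
class MaskConfig:
    """Parameters of the variable-density Cartesian undersampling scheme.

    acceleration
        Subsampling factor R; R=4 keeps 25% of lines, R=1 keeps all.
    central_fraction
        Fraction of the *sampled* lines taken contiguously at the k-space
        centre (default 0.20, i.e. a 20% central / 80% peripheral split).
    peripheral_decay_scale
        e-folding distance (in lines) of the peripheral sampling density;
        ``None`` means ``n_lines / 6``.
    axis
        Phase-encoding axis of each 2D slice (0 or 1).
    """

    acceleration: float = 4.0
    central_fraction: float = 0.20
    peripheral_decay_scale: float | None = None
    seed: int = 0
    axis: int = 0

    def __post_init__(self) -> None:
        if self.acceleration < 1:
            raise ValueError("acceleration must be >= 1")
        if not 0.0 < self.central_fraction < 1.0:
            raise ValueError("central_fraction must be in (0, 1)")
        if self.peripheral_decay_scale is not None and self.peripheral_decay_scale <= 0:
            raise ValueError("peripheral_decay_scale must be > 0")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1 (axis of a 2D slice)")


@dataclass(frozen=True)
class KSpaceMask:
    """A binary phase-encoding line mask in the centred frequency frame."""

    n_lines: int
    acceleration: float
    central_fraction: float
    sampled_lines: tuple[int, ...]
    seed: int = 0
    axis: int = 0

    def __post_init__(self) -> None:
        lines = tuple(sorted(int(i) for i in self.sampled_lines))
        if len(set(lines)) != len(lines):
            raise ValueError("sampled_lines contains duplicates")
        if lines and (lines[0] < 0 or lines[-1] >= self.n_lines):
            raise ValueError("sampled line index out of range")
        object.__setattr__(self, "sampled_lines", lines)

    @property
    def n_sampled(self) -> int:
        return len(self.sampled_lines)

    def as_array(self) -> np.ndarray:
        """Binary 1D array over the line axis (centred frequency frame)."""
        arr = np.zeros(self.n_lines, dtype=bool)
        arr[list(self.sampled_lines)] = True
        return arr

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_lines": self.n_lines,
                "acceleration": self.acceleration,
                "central_fraction": self.central_fraction,
                "seed": self.seed,
                "axis": self.axis,
                "sampled_lines": list(self.sampled_lines),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KSpaceMask":
        d = json.loads(text)
        return cls(
            n_lines=d["n_lines"],
            acceleration=d["acceleration"],
            central_fraction=d["central_fraction"],
            sampled_lines=tuple(d["sampled_lines"]),
            seed=d.get("seed", 0),
            axis=d.get("axis", 0),
        )


def central_band(n_lines: int, count: int) -> tuple[int, ...]:
    """Indices of the contiguous ``count``-line band centred on DC.

    The DC line is ``n_lines // 2``.  For even counts the extra line goes on
    the +k side (documented tie-break).
    """
    if count <= 0:
        return ()
    dc = n_lines // 2
    lo = dc - (count - 1) // 2
    hi = dc + count // 2
    return tuple(range(lo, hi + 1))


def make_undersampling_mask(n_lines: int, config: MaskConfig) -> KSpaceMask:
    """Build a variable-density Cartesian line mask.

    The sample budget is ``round(n_lines / R)`` (half away from zero); a
    contiguous band of ``round(central_fraction * budget)`` lines around DC
    is always included; the remaining lines are drawn without replacement
    from the periphery with weights ``exp(-distance / decay_scale)``
    (weighted-reservoir draw, deterministic given the seed).
    """
    if n_lines < 8:
        raise ValueError("n_lines must be >= 8")
    R = config.acceleration
    budget = _round_half_away(n_lines / R)
    if budget < 2:
        raise ValueError(f"acceleration {R} leaves fewer than 2 of {n_lines} lines")
    if R == 1:
        return KSpaceMask(
            n_lines=n_lines,
            acceleration=1.0,
            central_fraction=config.central_fraction,
            sampled_lines=tuple(range(n_lines)),
            seed=config.seed,
            axis=config.axis,
        )
    n_central = _round_half_away(config.central_fraction * budget)
    band = central_band(n_lines, n_central)
    n_peripheral = budget - len(band)
    if n_peripheral < 0:
        raise ValueError(
            f"central band ({len(band)} lines) exceeds the sample budget ({budget})"
        )
    periphery = np.setdiff1d(np.arange(n_lines), np.asarray(band, dtype=int))
    if n_peripheral > periphery.size:
        raise ValueError("peripheral budget exceeds available lines")
    dc = n_lines // 2
    scale = config.peripheral_decay_scale or n_lines / 6.0
    weights = np.exp(-np.abs(periphery - dc) / scale)
    # Efraimidis-Spirakis weighted reservoir: top-k keys u^(1/w) give a
    # without-replacement draw with the desired inclusion ordering.
    rng = np.random.default_rng(config.seed)
    keys = rng.random(periphery.size) ** (1.0 / weights)
    chosen = periphery[np.argsort(keys)[::-1][:n_peripheral]]
    sampled = tuple(sorted([*band, *chosen.tolist()]))
    return KSpaceMask(
        n_lines=n_lines,
        acceleration=R,
        central_fraction=config.central_fraction,
        sampled_lines=sampled,
        seed=config.seed,
        axis=config.axis,
    )


def pad_mask_for_zero_fill(
    mask: KSpaceMask, acquired_lines: int, padded_lines: int
) -> KSpaceMask:
    """Extend a mask over an acquired grid to a zero-filled (padded) grid.

    Scanner pipelines zero-fill peripheral k-space to interpolate to a finer
    grid; the binary mask must be zero-padded the same way so that the mask
    and the zero-filled data agree.  The inner region reproduces the input
    mask with DC lines aligned; the outer lines are never sampled.
    """
    if mask.n_lines != acquired_lines:
        raise ValueError("mask.n_lines must equal acquired_lines")
    if padded_lines < acquired_lines:
        raise ValueError("padded_lines must be >= acquired_lines")
    offset = padded_lines // 2 - acquired_lines // 2  # aligns the DC lines
    sampled = tuple(i + offset for i in mask.sampled_lines)
    return KSpaceMask(
        n_lines=padded_lines,
        acceleration=mask.acceleration,
        central_fraction=mask.central_fraction,
        sampled_lines=sampled,
        seed=mask.seed,
        axis=mask.axis,
    )


def undersample_slice(slice2d: np.ndarray, mask: KSpaceMask) -> np.ndarray:
    """Mask one 2D slice in k-space and return the magnitude of the IFFT."""
    if slice2d.shape[mask.axis] != mask.n_lines:
        raise ValueError(
            f"mask covers {mask.n_lines} lines but slice axis {mask.axis} "
            f"has extent {slice2d.shape[mask.axis]}"
        )
    ksp = np.fft.fftshift(np.fft.fft2(slice2d))
    line_mask = mask.as_array()
    if mask.axis == 0:
        ksp = ksp * line_mask[:, None]
    else:
        ksp = ksp * line_mask[None, :]
    return np.abs(np.fft.ifft2(np.fft.ifftshift(ksp)))


def undersample_volume(volume: ImageVolume, mask: KSpaceMask) -> ImageVolume:
    """Naive (zero-filled IFFT) reconstruction of an undersampled volume.

    Each 2D slice is transformed to k-space (DC centred), multiplied by the
    binary line mask broadcast across the frequency-encoding axis, and
    transformed back; the magnitude is taken because the pipeline works on
    magnitude (DICOM-derived) images.  Geometry is unchanged.  With R=1 the
    output equals the input to floating-point tolerance.
    """
    if volume.shape[mask.axis] != mask.n_lines:
        raise ValueError(
            f"mask covers {mask.n_lines} lines but volume axis {mask.axis} "
            f"has extent {volume.shape[mask.axis]}"
        )
    out = np.empty_like(volume.data)
    for k in range(volume.shape[2]):
        out[:, :, k] = undersample_slice(volume.data[:, :, k], mask)
    return volume.with_data(out)
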