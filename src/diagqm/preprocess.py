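"""Preprocessing chains for the reconstruction and detection stages.

Two fixed chains are used downstream:

* reconstruction chain — resample in-plane to 0.5 x 0.5 mm (z unchanged),
  centre-crop to (256, 256, 16), min/max normalise to [0, 1];
* detection chain — resample to (0.5, 0.5, 3.0) mm, centre-crop to
  (180, 180, 16), z-score normalise.

Crop sizes are configurable so the same chains run at desk scale on small
phantoms.  Lesion labelmaps always travel through the same resample/crop
with nearest-neighbour interpolation so they stay integer-labelled and
voxel-aligned with the image.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, LesionSet

__all__ = [
    "resample",
    "center_crop",
    "minmax_normalize",
    "z_normalize",
    "recon_chain",
    "detect_chain",
    "resample_labelmap",
    "center_crop_labelmap",
]

_SIGMA_FLOOR = 1e-8  # z-normalisation floor for (near-)constant volumes


def _target_shape(
    shape: tuple[int, ...], spacing: tuple[float, ...], target: tuple[float, ...]
) -> tuple[int, ...]:
    # Same physical extent re-gridded at the target spacing.
    return tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(shape, spacing, target)
    )


def _resample_array(
    data: np.ndarray,
    spacing: tuple[float, ...],
    target: tuple[float, ...],
    order: int,
) -> np.ndarray:
    new_shape = _target_shape(data.shape, spacing, target)
    if new_shape == data.shape:
        return data.copy()
    zoom = [n_new / n_old for n_new, n_old in zip(new_shape, data.shape)]
    out = ndimage.zoom(data, zoom, order=order, mode="nearest", grid_mode=True)
    assert out.shape == tuple(new_shape)
    return out


def resample(
    volume: ImageVolume,
    target_spacing: tuple[float, float, float],
    method: str = "nearest",
) -> ImageVolume:
    """Resample a volume to a new voxel spacing over the same physical extent.

    ``method`` is ``"nearest"`` (preserves the intensity value set; used by
    both chains, matching the scanner-export convention of the pipeline) or
    ``"linear"``.  A ``None`` entry in ``target_spacing`` leaves that axis
    unchanged.  When the input already has the target spacing the output is
    voxelwise identical.
    """
    if method not in ("nearest", "linear"):
        raise ValueError(f"method must be 'nearest' or 'linear', got {method!r}")
    tgt = tuple(
        volume.spacing[i] if target_spacing[i] is None else float(target_spacing[i])
        for i in range(3)
    )
    if any(t <= 0 for t in tgt):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if min(volume.shape) < 1:
        raise ValueError("degenerate volume")
    order = 0 if method == "nearest" else 1
    out = _resample_array(volume.data, volume.spacing, tgt, order)
    return ImageVolume(out, spacing=tgt, origin=volume.origin)


def resample_labelmap(
    lesions: LesionSet, target_spacing: tuple[float, float, float]
) -> LesionSet:
    """Nearest-neighbour resampling of a lesion labelmap (labels preserved)."""
    tgt = tuple(
        lesions.spacing[i] if target_spacing[i] is None else float(target_spacing[i])
        for i in range(3)
    )
    out = _resample_array(lesions.labelmap, lesions.spacing, tgt, order=0)
    return LesionSet(out, spacing=tgt, grades=dict(lesions.grades))


def _crop_pad_indices(n_in: int, n_out: int) -> tuple[slice, tuple[int, int]]:
    """Slice into the input and output padding for one axis.

    Tie-break: the extra voxel of an odd margin goes on the high-index side,
    for both cropping and padding, so image and labelmap stay aligned.
    """
    if n_in >= n_out:
        lo = (n_in - n_out) // 2
        return slice(lo, lo + n_out), (0, 0)
    pad_lo = (n_out - n_in) // 2
    return slice(0, n_in), (pad_lo, n_out - n_in - pad_lo)


def _center_crop_array(data: np.ndarray, size: tuple[int, int, int]) -> np.ndarray:
    if any(s <= 0 for s in size):
        raise ValueError(f"crop size must be positive, got {size}")
    slices, pads = zip(*(_crop_pad_indices(n, m) for n, m in zip(data.shape, size)))
    out = data[slices[0], slices[1], slices[2]]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode="constant")
    assert out.shape == tuple(size)
    return out


def center_crop(volume: ImageVolume, size: tuple[int, int, int]) -> ImageVolume:
    """Centre-crop (zero-padding smaller inputs) to an exact voxel size."""
    out = _center_crop_array(volume.data, size)
    return ImageVolume(out, spacing=volume.spacing, origin=volume.origin)


def center_crop_labelmap(lesions: LesionSet, size: tuple[int, int, int]) -> LesionSet:
    out = _center_crop_array(lesions.labelmap, size)
    return LesionSet(out, spacing=lesions.spacing, grades=dict(lesions.grades))


def minmax_normalize(volume: ImageVolume) -> ImageVolume:
    """Instance-wise min/max normalisation to [0, 1].

    A constant volume maps to all zeros (documented degenerate case).
    """
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi == lo:
        return volume.with_data(np.zeros_like(volume.data))
    return volume.with_data((volume.data - lo) / (hi - lo))


def z_normalize(volume: ImageVolume) -> ImageVolume:
    """Instance-wise z-score normalisation (mean 0, sd 1).

    A sigma floor of 1e-8 guards constant inputs (e.g. fully padded crops).
    Note the output is no longer a magnitude image: values may be negative.
    """
    mu = float(volume.data.mean())
    sd = max(float(volume.data.std()), _SIGMA_FLOOR)
    return volume.with_data((volume.data - mu) / sd)


def recon_chain(
    volume: ImageVolume,
    crop_size: tuple[int, int, int] = (256, 256, 16),
    in_plane_spacing: float = 0.5,
) -> ImageVolume:
    """Reconstruction-model chain: resample (z unchanged) -> crop -> min/max."""
    vol = resample(volume, (in_plane_spacing, in_plane_spacing, None), "nearest")
    vol = center_crop(vol, crop_size)
    return minmax_normalize(vol)


def detect_chain(
    volume: ImageVolume,
    crop_size: tuple[int, int, int] = (180, 180, 16),
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0),
) -> ImageVolume:
    """Detection-model chain: resample -> crop -> z-normalise."""
    vol = resample(volume, target_spacing, "nearest")
    vol = center_crop(vol, crop_size)
    return z_normalize(vol)


def recon_chain_labelmap(
    lesions: LesionSet,
    crop_size: tuple[int, int, int] = (256, 256, 16),
    in_plane_spacing: float = 0.5,
) -> LesionSet:
    """Reconstruction-chain geometry applied to the ground-truth labelmap."""
    out = resample_labelmap(lesions, (in_plane_spacing, in_plane_spacing, None))
    return center_crop_labelmap(out, crop_size)


def detect_chain_labelmap(
    lesions: LesionSet,
    crop_size: tuple[int, int, int] = (180, 180, 16),
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0),
) -> LesionSet:
    """Detection-chain geometry applied to the ground-truth labelmap."""
    out = resample_labelmap(lesions, target_spacing)
    return center_crop_labelmap(out, crop_size)
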