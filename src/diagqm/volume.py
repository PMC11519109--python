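"""Core in-memory containers: magnitude image volumes and lesion ground truth.

A volume is a 3D non-negative magnitude array indexed ``(x, y, z)`` together
with its voxel spacing in millimetres and a physical origin.  Slices are
``data[:, :, k]``; the third axis is the slice (through-plane) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "LesionSet"]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D magnitude MR volume with geometry metadata.

    Parameters
    ----------
    data:
        3D float array of magnitude intensities, all values >= 0.
    spacing:
        Voxel spacing in mm per axis, all > 0.
    origin:
        Physical position (mm) of the voxel at index (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same geometry, new intensities."""
        return replace(self, data=data)

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge-to-edge physical size of the voxel grid in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


@dataclass(frozen=True)
class LesionSet:
    """Per-patient labelled ground-truth lesions on a voxel grid.

    ``labelmap`` holds integer labels 1..n_lesions (0 = background) on the
    same grid as the patient's image.  ``grades`` maps each label to a
    reporting grade (PI-RADS style, 4 or 5 for likely clinically significant
    lesions).
    """

    labelmap: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grades: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lm = np.asarray(self.labelmap)
        if lm.ndim != 3:
            raise ValueError(f"labelmap must be 3D, got shape {lm.shape}")
        if not np.issubdtype(lm.dtype, np.integer):
            lm = lm.astype(np.int32)
        object.__setattr__(self, "labelmap", lm)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def labels(self) -> list[int]:
        """Sorted lesion labels present in the map (background excluded)."""
        present = np.unique(self.labelmap)
        return [int(v) for v in present if v != 0]

    @property
    def n_lesions(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n_lesions

    def mask(self, label: int) -> np.ndarray:
        """Binary voxel mask of one lesion."""
        return self.labelmap == label

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labelmap == label))
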