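"""Volume I/O: NIfTI read/write and DICOM-series reading.

NIfTI is the working format (images and labelmaps); DICOM series are read
the way scanner exports arrive — one 2D file per slice, sorted along the
normal, spacing taken from PixelSpacing and the slice positions.  Geometry
is kept as (spacing, origin); save/load round-trips preserve intensities to
float32 and spacing to 1e-4 mm.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import ImageVolume, LesionSet

__all__ = ["load_volume", "save_volume", "load_labelmap", "save_labelmap"]


class VolumeReadError(RuntimeError):
    """Raised when a path cannot be read as a single coherent volume."""


def _affine(volume: ImageVolume) -> np.ndarray:
    aff = np.diag([*volume.spacing, 1.0])
    aff[:3, 3] = volume.origin
    return aff


def save_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (float32 intensities)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume))
    nib.save(img, str(path))
    return path


def save_labelmap(lesions: LesionSet, path: str | Path) -> Path:
    """Write a lesion labelmap as integer NIfTI."""
    path = Path(path)
    aff = np.diag([*lesions.spacing, 1.0])
    img = nib.Nifti1Image(lesions.labelmap.astype(np.int16), aff)
    nib.save(img, str(path))
    return path


def _load_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeReadError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeReadError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, spacing=tuple(float(z) for z in zooms), origin=origin)


def load_labelmap(path: str | Path) -> LesionSet:
    vol = _load_nifti(Path(path))
    return LesionSet(np.rint(vol.data).astype(np.int16), spacing=vol.spacing)


def _load_dicom_series(directory: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue  # non-DICOM clutter in the directory
    if not datasets:
        raise VolumeReadError(f"no readable DICOM files in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise VolumeReadError(
            f"{directory} mixes {len(uids)} DICOM series; split them first"
        )
    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise VolumeReadError(
                f"{directory}: missing PixelSpacing (0028,0030) in a slice"
            )

    def sort_key(ds) -> float:
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    first = datasets[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        positions = [sort_key(ds) for ds in datasets]
        slice_sp = float(np.median(np.diff(positions)))
        if slice_sp <= 0:
            slice_sp = float(getattr(first, "SliceThickness", 1.0))
    else:
        slice_sp = float(getattr(first, "SliceThickness", 1.0))
    data = np.stack([ds.pixel_array.astype(np.float64) for ds in datasets], axis=2)
    # DICOM rows run along the first pixel-array axis: spacing is (row, col)
    return ImageVolume(data, spacing=(row_sp, col_sp, slice_sp))


def load_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory as an ImageVolume."""
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    if not path.exists():
        raise VolumeReadError(f"{path} does not exist")
    return _load_nifti(path)
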