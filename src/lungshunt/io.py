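"""Volume and sidecar I/O.

Volumes are stored as NIfTI (``.nii``/``.nii.gz``, via nibabel) or MetaImage
(``.mha``/``.mhd``, via SimpleITK).  Arrays are indexed ``(x, y, z)`` with the
third axis running inferior -> superior; the voxel spacing in mm is carried in
the image header.  Tabular results are CSV with JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _full_suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def save_volume(path: str | Path, array: np.ndarray, voxel_spacing_mm) -> Path:
    """Write a 3-D array with its voxel spacing (mm) to NIfTI or MetaImage."""
    path = Path(path)
    spacing = np.asarray(voxel_spacing_mm, dtype=float)
    if spacing.ndim == 0:
        spacing = np.repeat(spacing, 3)
    suffix = _full_suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))
    elif suffix in _META_SUFFIXES:
        # SimpleITK uses (z, y, x) array order
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 1, 0))))
        img.SetSpacing(tuple(float(s) for s in spacing))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name!r}")
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a volume; returns ``(array, voxel_spacing_mm)`` in (x, y, z) order."""
    path = Path(path)
    suffix = _full_suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        array = np.asarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    elif suffix in _META_SUFFIXES:
        img = sitk.ReadImage(str(path))
        array = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = np.asarray(img.GetSpacing(), dtype=float)
    else:
        raise ValueError(f"unsupported volume format: {path.name!r}")
    return array, spacing


def save_json(path: str | Path, obj) -> Path:
    """Serialize ``obj`` to pretty, key-sorted (hence byte-reproducible) JSON."""
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n")
    return path


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"cannot serialize {type(obj).__name__}")
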