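"""Volume readers/writers (NIfTI and MetaImage) and dynamic-series I/O.

Geometry convention: 0-based voxel indices, array axis order (x, y, z),
world coordinates voxel-centred, isotropic spacing in mm.  NIfTI is
handled by nibabel, MetaImage (.mha/.mhd) by SimpleITK.  A 4D dynamic
series is a 4D volume plus a JSON sidecar carrying the frame mid-times.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .volumes import TimeActivitySeries, Volume, f18_decay_constant

__all__ = ["read_volume", "write_volume", "read_series", "write_series"]


def _is_nifti(path: Path) -> bool:
    s = "".join(path.suffixes[-2:])
    return s.endswith(".nii") or s.endswith(".nii.gz")


def _is_metaimage(path: Path) -> bool:
    return path.suffix in (".mha", ".mhd")


def _check_isotropic(spacing) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-5):
        warnings.warn(f"anisotropic spacing {tuple(spacing)}; using the "
                      "first component")
    return float(spacing[0])


def read_volume(path) -> Volume:
    """Read a 3D volume with spacing and origin."""
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path} is not a 3D volume (shape {data.shape})")
        spacing = _check_isotropic(img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return Volume(data, spacing_mm=spacing, origin_mm=origin)
    if _is_metaimage(path):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
        spacing = _check_isotropic(img.GetSpacing())
        return Volume(data, spacing_mm=spacing,
                      origin_mm=tuple(img.GetOrigin()))
    raise ValueError(f"unsupported volume format: {path.name} "
                     "(expected .nii, .nii.gz, .mha or .mhd)")


def write_volume(volume: Volume, path) -> None:
    """Write a 3D volume; format chosen by extension."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([volume.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64),
                                 affine), str(path))
        return
    if _is_metaimage(path):
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(volume.data.transpose(2, 1, 0),
                                 dtype=np.float64))
        img.SetSpacing((volume.spacing_mm,) * 3)
        img.SetOrigin(tuple(volume.origin_mm))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii", ".mha", ".mhd"):
        if name.endswith(suf):
            return path.with_name(name[:-len(suf)] + ".json")
    return path.with_suffix(".json")


def write_series(series: TimeActivitySeries, path) -> None:
    """Write a dynamic series as a 4D NIfTI plus a JSON time sidecar."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError("dynamic series are written as NIfTI")
    data = np.moveaxis(series.frames, 0, -1)  # (x, y, z, t)
    affine = np.diag([series.spacing_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))
    _sidecar(path).write_text(json.dumps({
        "times_min": list(map(float, series.times_min)),
        "decay_constant_per_min": series.decay_constant_per_min,
    }))


def read_series(path) -> TimeActivitySeries:
    """Read a 4D dynamic series; frame times come from the JSON sidecar."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D series")
    spacing = _check_isotropic(img.header.get_zooms()[:3])
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        times = np.asarray(meta["times_min"], dtype=float)
        lam = float(meta.get("decay_constant_per_min", f18_decay_constant()))
    else:
        raise ValueError(f"missing time sidecar {side.name} for {path.name}")
    return TimeActivitySeries(times_min=times,
                              frames=np.moveaxis(data, -1, 0),
                              spacing_mm=spacing,
                              decay_constant_per_min=lam)
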