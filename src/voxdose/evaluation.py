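"""Quantitative-analysis toolbox for comparing dose maps and kernels.

Voxelwise error metrics (MAE, MRAE, RMSE), Bland-Altman limits of
agreement, joint-histogram R^2, fixed-threshold lesion segmentation, VOI
dosimetry and line profiles.  All operations take aligned arrays (or
Volume-like objects exposing ``.data``) and an optional boolean mask.

The MRAE masking rule: voxels whose reference magnitude is below
``1e-3 * max|ref|`` are excluded from relative errors (and from
Bland-Altman percent differences); the number of voxels actually used is
reported alongside every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricsResult", "AgreementResult", "voxel_metrics",
           "bland_altman", "joint_histogram_r2", "segment_lesion_suv",
           "voi_mean_dose", "line_profile", "MRAE_REFERENCE_FLOOR"]

MRAE_REFERENCE_FLOOR = 1e-3  # fraction of max |reference|


def _arr(x) -> np.ndarray:
    return np.asarray(getattr(x, "data", x), dtype=float)


def _masked(pred, ref, mask):
    pred = _arr(pred)
    ref = _arr(ref)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes differ")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    else:
        mask = np.asarray(getattr(mask, "data", mask)).astype(bool)
        if mask.shape != pred.shape:
            raise ValueError("mask shape differs")
    if not mask.any():
        raise ValueError("empty mask")
    return pred[mask], ref[mask]


@dataclass
class MetricsResult:
    """MAE/RMSE in the input units, MRAE in percent."""

    mae: float
    mrae_pct: float
    rmse: float
    n_voxels: int
    n_voxels_mrae: int
    mask_descriptor: str = ""


@dataclass
class AgreementResult:
    """Bland-Altman bias and 95% limits of agreement (percent of reference)."""

    bias_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    n_voxels: int
    differences_pct: np.ndarray | None = None


def voxel_metrics(pred, ref, mask=None,
                  mask_descriptor: str = "") -> MetricsResult:
    """MAE, MRAE(%) and RMSE between predicted and reference volumes.

    MRAE excludes voxels with reference below the floor (near-zero
    denominators); MAE/RMSE use every masked voxel.
    """
    p, r = _masked(pred, ref, mask)
    err = p - r
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    floor = MRAE_REFERENCE_FLOOR * np.max(np.abs(r)) if r.size else 0.0
    ok = np.abs(r) > floor
    if not ok.any():
        raise ValueError("no voxels above the MRAE reference floor")
    mrae = float(np.mean(np.abs(err[ok] / r[ok])) * 100.0)
    return MetricsResult(mae=mae, mrae_pct=mrae, rmse=rmse,
                         n_voxels=int(p.size), n_voxels_mrae=int(ok.sum()),
                         mask_descriptor=mask_descriptor)


def bland_altman(pred, ref, mask=None,
                 keep_differences: bool = False) -> AgreementResult:
    """Bland-Altman agreement on voxelwise percent differences.

    Differences are (pred - ref)/ref * 100; bias is their mean and the 95%
    limits of agreement are bias +/- 1.96 SD.
    """
    p, r = _masked(pred, ref, mask)
    floor = MRAE_REFERENCE_FLOOR * np.max(np.abs(r)) if r.size else 0.0
    ok = np.abs(r) > floor
    if ok.sum() < 2:
        raise ValueError("Bland-Altman needs at least 2 usable voxels")
    d = (p[ok] - r[ok]) / r[ok] * 100.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(bias_pct=bias,
                           loa_lower_pct=bias - 1.96 * sd,
                           loa_upper_pct=bias + 1.96 * sd,
                           n_voxels=int(ok.sum()),
                           differences_pct=d if keep_differences else None)


def joint_histogram_r2(pred, ref, mask=None) -> float:
    """Coefficient of determination of the least-squares fit of pred on ref."""
    p, r = _masked(pred, ref, mask)
    if np.unique(r).size < 2:
        raise ValueError("reference needs at least 2 distinct values")
    slope, intercept = np.polyfit(r, p, 1)
    fit = slope * r + intercept
    ss_res = np.sum((p - fit) ** 2)
    ss_tot = np.sum((p - p.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(1.0 - ss_res / ss_tot)


def segment_lesion_suv(pet, fraction: float = 0.42,
                       seed_region=None) -> np.ndarray:
    """Fixed-threshold lesion segmentation at a fraction of the regional max.

    The mask is the 26-connected component of voxels with uptake >=
    fraction * max (max taken inside ``seed_region`` when given) that
    contains the maximum voxel.
    """
    img = _arr(pet)
    region = (np.ones(img.shape, dtype=bool) if seed_region is None
              else np.asarray(getattr(seed_region, "data",
                                      seed_region)).astype(bool))
    vals = np.where(region, img, -np.inf)
    peak = vals.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("seed region has no positive uptake")
    above = img >= fraction * peak
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    peak_idx = np.unravel_index(int(np.argmax(vals)), img.shape)
    return labels == labels[peak_idx]


def voi_mean_dose(dose, mask) -> tuple[float, float]:
    """Mean and SD of dose over a volume of interest."""
    d = _arr(dose)
    m = np.asarray(getattr(mask, "data", mask)).astype(bool)
    if not m.any():
        raise ValueError("empty VOI")
    vals = d[m]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(np.mean(vals)), sd


def line_profile(volume, axis: int, fixed_indices: tuple[int, int],
                 spacing_mm: float | None = None):
    """Values along one grid axis with physical (mm) coordinates attached.

    ``fixed_indices`` are the indices of the two remaining axes in order.
    Returns (coordinates_mm, values).
    """
    data = _arr(volume)
    if spacing_mm is None:
        spacing_mm = float(getattr(volume, "spacing_mm", 1.0))
    if not 0 <= axis < 3:
        raise ValueError("axis must be 0, 1 or 2")
    others = [a for a in range(3) if a != axis]
    for a, idx in zip(others, fixed_indices):
        if not 0 <= idx < data.shape[a]:
            raise IndexError(f"index {idx} out of range for axis {a}")
    sl = [None, None, None]
    sl[axis] = slice(None)
    sl[others[0]], sl[others[1]] = fixed_indices
    values = data[tuple(sl)]
    coords = (np.arange(data.shape[axis]) + 0.5) * spacing_mm
    return coords, values
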