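"""Whole-body absorbed-dose construction (voxel-MIRD formalism).

The dose to a target voxel k is the superposition over source voxels h of
the cumulated activity times the voxel S-value kernel,

    D(k) = sum_h  A_tilde(h) * S(k <- h),

with A_tilde the time-integrated number of disintegrations per voxel.  Three
engines share this formalism and differ only in the kernel:

* ``dose_ssv``      - one homogeneous soft-tissue kernel, FFT convolution;
* ``dose_msv``      - one homogeneous kernel per tissue medium, combined by
                      binary masks of the segmented media;
* ``dose_specific`` - a patch-specific kernel per source voxel (Monte Carlo
                      oracle or learned predictor), scatter-added.

Tallies in MeV/cm^3 are converted to Gy with the beta+ branching factor
0.9673 and 1 MeV = 1.602176634e-13 J.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import fftconvolve

from .constants import (F18_POSITRON_FRACTION, MEV_PER_CM3_TO_GY_PER_DENSITY)
from .cross_sections import CrossSectionTable, default_cross_sections
from .materials import default_material_table
from .phantoms import extract_patch
from .volumes import DoseMap, TimeActivitySeries, Volume

logger = logging.getLogger(__name__)

__all__ = ["cumulate_activity", "dose_ssv", "dose_msv", "dose_specific",
           "tally_to_gray", "convolve_kernel"]


def cumulate_activity(series: TimeActivitySeries,
                      printed_sum: bool = False) -> Volume:
    """Per-voxel total disintegrations: quadrature over frames plus decay tail.

    The frame integral is the trapezoidal rule over the 13 frame mid-times;
    after the last frame the activity is assumed to decay physically, adding
    the analytic tail A_f / lambda.  Concentrations (Bq/mL) are converted to
    decays with the voxel volume and 60 s/min.

    ``printed_sum=True`` drops the 1/2 factor of the trapezoid, i.e. uses
    the literal sum  (A_i + A_{i+1}) * dt_i  instead of its half.
    """
    t = series.times_min
    frames = series.frames
    lam = series.decay_constant_per_min
    if frames.shape[0] == 1:
        integral = np.zeros(frames.shape[1:])
    else:
        integral = np.trapezoid(frames, t, axis=0)
        if printed_sum:
            integral = integral * 2.0
    integral = integral + frames[-1] / lam
    vol_ml = Volume(frames[0], series.spacing_mm).voxel_volume_cm3
    decays = integral * 60.0 * vol_ml  # Bq*min/mL -> decays per voxel
    return Volume(decays, spacing_mm=series.spacing_mm)


def tally_to_gray(tally_mev_per_cm3, total_decays: float,
                  density: Volume) -> np.ndarray:
    """Convert a deposition tally to absorbed dose in Gy.

    Gy = tally * decays * 0.9673 * 1.602176634e-10 / rho, voxelwise.
    """
    tally = np.asarray(tally_mev_per_cm3, dtype=float)
    rho = np.asarray(density.data, dtype=float)
    if np.any((rho <= 0) & (tally != 0)):
        raise ValueError("nonzero tally in zero-density voxel")
    safe_rho = np.where(rho > 0, rho, 1.0)
    return (tally * float(total_decays) * F18_POSITRON_FRACTION
            * MEV_PER_CM3_TO_GY_PER_DENSITY / safe_rho)


def convolve_kernel(activity: np.ndarray, kernel_dep: np.ndarray,
                    source_index, method: str = "fft") -> np.ndarray:
    """sum_h act[h] * K[k - h + src]; zero-padded boundaries.

    ``method='direct'`` is the brute-force nested sum (oracle for tests).
    """
    src = tuple(int(s) for s in source_index)
    if method == "fft":
        full = fftconvolve(activity, kernel_dep, mode="full")
        out = full[src[0]:src[0] + activity.shape[0],
                   src[1]:src[1] + activity.shape[1],
                   src[2]:src[2] + activity.shape[2]]
        return np.clip(out, 0.0, None)
    if method == "direct":
        out = np.zeros_like(activity, dtype=float)
        nx, ny, nz = activity.shape
        kx, ky, kz = kernel_dep.shape
        for h in np.argwhere(activity != 0):
            a = activity[tuple(h)]
            for j0 in range(kx):
                k0 = h[0] + j0 - src[0]
                if not 0 <= k0 < nx:
                    continue
                for j1 in range(ky):
                    k1 = h[1] + j1 - src[1]
                    if not 0 <= k1 < ny:
                        continue
                    for j2 in range(kz):
                        k2 = h[2] + j2 - src[2]
                        if 0 <= k2 < nz:
                            out[k0, k1, k2] += a * kernel_dep[j0, j1, j2]
        return out
    raise ValueError(f"unknown method {method!r}")


def dose_ssv(cum: Volume, kernel, density: Volume,
             method: str = "fft") -> DoseMap:
    """Single-voxel-S-value dose: one soft-tissue kernel for every voxel."""
    cum.require_same_grid(density, "activity and density")
    if abs(kernel.spacing_mm - cum.spacing_mm) > 1e-9:
        raise ValueError("kernel and grid spacing differ")
    tally = convolve_kernel(cum.data, kernel.deposition, kernel.source_index,
                            method)
    gy = tally_to_gray(tally, 1.0, density)
    return DoseMap(gy, spacing_mm=cum.spacing_mm, engine="ssv",
                   params={"kernel": kernel.medium,
                           "histories": kernel.histories})


def dose_msv(cum: Volume, library, materials: Volume, density: Volume,
             method: str = "fft") -> DoseMap:
    """Multiple-voxel-S-value dose: per-medium convolution masked and summed.

    Each of the 13 material classes is mapped to the nearest-density medium
    of the library (the 13 -> 4 reduction); each medium's convolution
    contributes only inside its own binary mask.
    """
    cum.require_same_grid(density, "activity and density")
    if not library.kernels:
        raise ValueError("empty kernel library")
    mt = default_material_table()
    media = sorted(library.kernels)
    med_density = np.array([mt.material(m).density for m in media])
    class_to_medium = np.array([
        media[int(np.argmin(np.abs(med_density - mt.material(c).density)))]
        for c in range(len(mt))
    ])
    mapped = class_to_medium[materials.data.astype(int)]
    tally = np.zeros(cum.shape)
    for m in media:
        kern = library.kernels[m]
        conv = convolve_kernel(cum.data, kern.deposition, kern.source_index,
                               method)
        tally[mapped == m] = conv[mapped == m]
    gy = tally_to_gray(tally, 1.0, density)
    return DoseMap(gy, spacing_mm=cum.spacing_mm, engine="msv",
                   params={"media": media})


def dose_specific(cum: Volume, provider, density: Volume,
                  materials: Volume | None = None,
                  reciprocity_correction: bool | None = None,
                  xs: CrossSectionTable | None = None) -> DoseMap:
    """Specific-kernel dose: per-source-voxel kernels, scatter-added.

    For every source voxel with nonzero cumulated activity, the provider
    yields the kernel of the 64^3 density patch centred there; the
    energy-absorption-ratio correction is applied when the provider's
    kernels are not simulated in the actual patch (learned mode), then
    A_tilde * kernel is scatter-added into the dose grid.
    """
    from .kernels import apply_reciprocity_correction

    cum.require_same_grid(density, "activity and density")
    mt = default_material_table()
    if materials is None:
        materials = Volume(mt.classify_material(density.data),
                           spacing_mm=density.spacing_mm)
    if reciprocity_correction is None:
        reciprocity_correction = getattr(provider,
                                         "needs_reciprocity_correction", False)
    xs = xs or default_cross_sections()

    src = None
    pad = None
    out = None
    skipped_air = 0
    sources = np.argwhere(cum.data > 0)
    for h in sources:
        h = tuple(int(v) for v in h)
        if materials.data[h] == 0:
            skipped_air += 1
            continue
        patch = extract_patch(density, h)
        kernel = provider.kernel_for(patch)
        if src is None:
            src = kernel.source_index
            ks = kernel.shape[0]
            pad = ks
            out = np.zeros(tuple(n + 2 * pad for n in cum.shape))
        dep = kernel.deposition
        if reciprocity_correction:
            mpatch = extract_patch(materials, h, pad_value=0)
            dep = apply_reciprocity_correction(
                kernel, int(materials.data[h]), mpatch.data, xs=xs).deposition
        lo = tuple(h[a] - src[a] + pad for a in range(3))
        out[lo[0]:lo[0] + ks, lo[1]:lo[1] + ks, lo[2]:lo[2] + ks] += \
            cum.data[h] * dep
    if skipped_air:
        logger.info("dose_specific: skipped %d air-voxel sources", skipped_air)
    if out is None:
        tally = np.zeros(cum.shape)
    else:
        tally = out[pad:pad + cum.shape[0], pad:pad + cum.shape[1],
                    pad:pad + cum.shape[2]]
    gy = tally_to_gray(tally, 1.0, density)
    return DoseMap(gy, spacing_mm=cum.spacing_mm, engine="specific",
                   params={"provider": getattr(provider, "mode", "unknown"),
                           "skipped_air_sources": skipped_air,
                           "reciprocity_correction": bool(
                               reciprocity_correction)})
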