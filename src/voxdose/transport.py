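"""Simplified Monte Carlo engine for voxel S-value kernels and direct dose maps.

Per decay, a positron is sampled from the F-18 beta+ spectrum and deposits
its kinetic energy along a straight track over the CSDA range in the local
density, after which two back-to-back 511 keV annihilation photons are
emitted isotropically.  Photons are tracked voxel-by-voxel (Amanatides-Woo
ray traversal with the local linear attenuation coefficient), undergoing
Klein-Nishina Compton scattering and photoelectric absorption, and are
terminated below 10 keV with local deposition.

Boundary modes:

* ``vacuum``   - photons leaving the grid escape (patch-specific kernels and
  whole-body dose maps: nothing scatters back from outside the volume);
* ``infinite`` - the homogeneous medium extends forever and only the tally
  mesh is finite (how the homogeneous SSV/MSV kernels are defined); photons
  wander freely and are killed far outside the mesh once any return
  contribution is negligible.

Two estimators are scored simultaneously:

* photon kerma - a track-length energy-deposition mesh tally
  ``E * mu_en(E) * path`` (the low-variance heating estimator), plus exact
  local deposits from sub-cutoff photons;
* analog      - collision-by-collision deposition which, with the escape
  tally, conserves energy exactly per history.

Positron energy deposition is tallied on its own grid so the photon heating
field and the positron self-dose can be separated.  Histories are grouped
into batches; per-voxel relative standard errors come from batch statistics.
Runs are reproducible for fixed (seed, histories, batches), single-threaded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import (ANNIHILATION_KEV, KERNEL_SHAPE, KERNEL_SPACING_MM,
                        PHOTON_CUTOFF_KEV, SOURCE_INDEX)
from .cross_sections import CrossSectionTable, default_cross_sections
from .materials import default_material_table
from .spectrum import default_spectrum
from .volumes import DoseMap, Volume, VoxelKernel

__all__ = ["simulate_kernel", "simulate_point_source", "simulate_direct_dose",
           "estimate_uncertainty", "border_to_center_ratio",
           "TransportResult"]

# CSDA range of electrons/positrons in water (kinetic energy keV -> g/cm^2),
# log-log interpolated.  Positron ranges differ from these by a few percent,
# well within the straight-track simplification.
_RANGE_E_KEV = np.array([10.0, 20.0, 50.0, 100.0, 200.0, 300.0, 400.0,
                         500.0, 633.5, 800.0])
_RANGE_G_CM2 = np.array([2.6e-4, 9.0e-4, 4.5e-3, 1.45e-2, 4.5e-2, 8.4e-2,
                         1.29e-1, 1.77e-1, 2.44e-1, 3.3e-1])

_INF = 1e30


@njit(cache=True, inline="always")
def _interp_loglog(x, logx, logy):
    lx = np.log(x)
    n = logx.size
    if lx <= logx[0]:
        j = 0
    elif lx >= logx[n - 1]:
        j = n - 2
    else:
        j = np.searchsorted(logx, lx) - 1
    w = (lx - logx[j]) / (logx[j + 1] - logx[j])
    return np.exp(logy[j] * (1.0 - w) + logy[j + 1] * w)


@njit(cache=True, inline="always")
def _coeff(tbl, m, e_kev, loge0, dlog):
    """Linear interpolation of a dense (n_mat, n_e) coefficient table."""
    f = (np.log(e_kev) - loge0) / dlog
    ne = tbl.shape[1]
    if f < 0.0:
        f = 0.0
    if f > ne - 1.0:
        f = ne - 1.0
    j = int(f)
    if j >= ne - 1:
        j = ne - 2
    w = f - j
    return tbl[m, j] * (1.0 - w) + tbl[m, j + 1] * w


@njit(cache=True, inline="always")
def _isotropic():
    cost = 2.0 * np.random.random() - 1.0
    sint = np.sqrt(1.0 - cost * cost)
    phi = 2.0 * np.pi * np.random.random()
    return sint * np.cos(phi), sint * np.sin(phi), cost


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = np.cos(phi)
    sphi = np.sin(phi)
    if abs(uz) < 0.999999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = ux * cost + sint * (ux * uz * cphi - uy * sphi) / denom
        vy = uy * cost + sint * (uy * uz * cphi + ux * sphi) / denom
        vz = uz * cost - sint * denom * cphi
    else:
        vx = sint * cphi
        vy = sint * sphi
        vz = cost if uz > 0 else -cost
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True, inline="always")
def _sample_compton(alpha):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (eps, cost) with eps = E'/E.
    """
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (1.0 + 2.0 * alpha) / (9.0 + 2.0 * alpha):
            x = 1.0 + 2.0 * alpha * r2  # x = E/E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return 1.0 / x, 1.0 - (x - 1.0) / alpha
        else:
            x = (1.0 + 2.0 * alpha) / (1.0 + 2.0 * alpha * r2)
            cost = 1.0 - (x - 1.0) / alpha
            if r3 <= 0.5 * (cost * cost + 1.0 / x):
                return 1.0 / x, cost


@njit(cache=True)
def _sample_spectrum(cdf, energies):
    u = np.random.random()
    n = cdf.size
    if u <= cdf[0]:
        return energies[0]
    j = np.searchsorted(cdf, u) - 1
    if j >= n - 1:
        return energies[n - 1]
    w = (u - cdf[j]) / (cdf[j + 1] - cdf[j] + 1e-300)
    return energies[j] * (1.0 - w) + energies[j + 1] * w


@njit(cache=True)
def _track_photon(x, y, z, ux, uy, uz, e_kev, density, mats,
                  mu_tbl, pe_tbl, muen_tbl, loge0, dlog, h_cm,
                  kerma, analog, cutoff_kev):
    """Track one photon in a vacuum-bounded grid; returns escaped keV."""
    nx, ny, nz = density.shape
    while True:
        ix = int(np.floor(x / h_cm))
        iy = int(np.floor(y / h_cm))
        iz = int(np.floor(z / h_cm))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            return e_kev
        stepx = 1 if ux > 0 else -1
        stepy = 1 if uy > 0 else -1
        stepz = 1 if uz > 0 else -1
        tmaxx = ((ix + (1 if ux > 0 else 0)) * h_cm - x) / ux if ux != 0.0 else _INF
        tmaxy = ((iy + (1 if uy > 0 else 0)) * h_cm - y) / uy if uy != 0.0 else _INF
        tmaxz = ((iz + (1 if uz > 0 else 0)) * h_cm - z) / uz if uz != 0.0 else _INF
        tdx = h_cm / abs(ux) if ux != 0.0 else _INF
        tdy = h_cm / abs(uy) if uy != 0.0 else _INF
        tdz = h_cm / abs(uz) if uz != 0.0 else _INF

        tau = -np.log(np.random.random())
        acc = 0.0
        t = 0.0
        interacted = False
        while True:
            tnext = min(tmaxx, tmaxy, tmaxz)
            seg = tnext - t
            rho = density[ix, iy, iz]
            m = mats[ix, iy, iz]
            mu = _coeff(mu_tbl, m, e_kev, loge0, dlog) * rho
            muen = _coeff(muen_tbl, m, e_kev, loge0, dlog) * rho
            if acc + mu * seg >= tau:
                d = (tau - acc) / mu
                kerma[ix, iy, iz] += e_kev * muen * d
                t += d
                x += t * ux
                y += t * uy
                z += t * uz
                interacted = True
                break
            kerma[ix, iy, iz] += e_kev * muen * seg
            acc += mu * seg
            t = tnext
            if tmaxx <= tmaxy and tmaxx <= tmaxz:
                ix += stepx
                tmaxx += tdx
                if ix < 0 or ix >= nx:
                    return e_kev
            elif tmaxy <= tmaxz:
                iy += stepy
                tmaxy += tdy
                if iy < 0 or iy >= ny:
                    return e_kev
            else:
                iz += stepz
                tmaxz += tdz
                if iz < 0 or iz >= nz:
                    return e_kev
        if not interacted:
            return e_kev

        m = mats[ix, iy, iz]
        mu_t = _coeff(mu_tbl, m, e_kev, loge0, dlog)
        mu_pe = _coeff(pe_tbl, m, e_kev, loge0, dlog)
        if np.random.random() * mu_t < mu_pe:
            analog[ix, iy, iz] += e_kev
            return 0.0
        eps, cost = _sample_compton(e_kev / 511.0)
        e_new = e_kev * eps
        analog[ix, iy, iz] += e_kev - e_new
        if e_new < cutoff_kev:
            analog[ix, iy, iz] += e_new
            kerma[ix, iy, iz] += e_new
            return 0.0
        phi = 2.0 * np.pi * np.random.random()
        ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
        e_kev = e_new


@njit(cache=True)
def _score_segment_hom(x, y, z, ux, uy, uz, s, val_per_cm, h_cm,
                       nx, ny, nz, kerma):
    """Score ``val_per_cm * length`` along the part of a segment inside the mesh."""
    tmin = 0.0
    tmax = s
    for axis in range(3):
        if axis == 0:
            u = ux
            p = x
            n = nx
        elif axis == 1:
            u = uy
            p = y
            n = ny
        else:
            u = uz
            p = z
            n = nz
        lo = 0.0
        hi = n * h_cm
        if u == 0.0:
            if p < lo or p >= hi:
                return
        else:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmin >= tmax:
        return
    # march from tmin to tmax
    eps = 1e-9
    t = tmin + eps
    px = x + t * ux
    py = y + t * uy
    pz = z + t * uz
    ix = int(np.floor(px / h_cm))
    iy = int(np.floor(py / h_cm))
    iz = int(np.floor(pz / h_cm))
    if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
        return
    stepx = 1 if ux > 0 else -1
    stepy = 1 if uy > 0 else -1
    stepz = 1 if uz > 0 else -1
    tmaxx = ((ix + (1 if ux > 0 else 0)) * h_cm - x) / ux if ux != 0.0 else _INF
    tmaxy = ((iy + (1 if uy > 0 else 0)) * h_cm - y) / uy if uy != 0.0 else _INF
    tmaxz = ((iz + (1 if uz > 0 else 0)) * h_cm - z) / uz if uz != 0.0 else _INF
    tdx = h_cm / abs(ux) if ux != 0.0 else _INF
    tdy = h_cm / abs(uy) if uy != 0.0 else _INF
    tdz = h_cm / abs(uz) if uz != 0.0 else _INF
    while True:
        tnext = min(tmaxx, tmaxy, tmaxz)
        hi = tnext if tnext < tmax else tmax
        if hi > t:
            kerma[ix, iy, iz] += val_per_cm * (hi - t)
        if tnext >= tmax:
            return
        t = tnext
        if tmaxx <= tmaxy and tmaxx <= tmaxz:
            ix += stepx
            tmaxx += tdx
            if ix < 0 or ix >= nx:
                return
        elif tmaxy <= tmaxz:
            iy += stepy
            tmaxy += tdy
            if iy < 0 or iy >= ny:
                return
        else:
            iz += stepz
            tmaxz += tdz
            if iz < 0 or iz >= nz:
                return


@njit(cache=True)
def _track_photon_infinite(x, y, z, ux, uy, uz, e_kev, m, rho,
                           mu_tbl, pe_tbl, muen_tbl, loge0, dlog, h_cm,
                           nx, ny, nz, kerma, analog, cutoff_kev,
                           kill_radius_cm):
    """Track one photon in an unbounded homogeneous medium.

    Only the finite mesh is tallied; deposition outside it is returned (it
    plays the role of the escape tally).
    """
    cx = 0.5 * nx * h_cm
    cy = 0.5 * ny * h_cm
    cz = 0.5 * nz * h_cm
    outside_dep = 0.0
    while True:
        mu = _coeff(mu_tbl, m, e_kev, loge0, dlog) * rho
        muen = _coeff(muen_tbl, m, e_kev, loge0, dlog) * rho
        s = -np.log(np.random.random()) / mu
        _score_segment_hom(x, y, z, ux, uy, uz, s, e_kev * muen, h_cm,
                           nx, ny, nz, kerma)
        x += s * ux
        y += s * uy
        z += s * uz
        dx = x - cx
        dy = y - cy
        dz = z - cz
        if dx * dx + dy * dy + dz * dz > kill_radius_cm * kill_radius_cm:
            return outside_dep + e_kev
        ix = int(np.floor(x / h_cm))
        iy = int(np.floor(y / h_cm))
        iz = int(np.floor(z / h_cm))
        inside = (0 <= ix < nx) and (0 <= iy < ny) and (0 <= iz < nz)
        mu_t = _coeff(mu_tbl, m, e_kev, loge0, dlog)
        mu_pe = _coeff(pe_tbl, m, e_kev, loge0, dlog)
        if np.random.random() * mu_t < mu_pe:
            if inside:
                analog[ix, iy, iz] += e_kev
            else:
                outside_dep += e_kev
            return outside_dep
        eps, cost = _sample_compton(e_kev / 511.0)
        e_new = e_kev * eps
        if inside:
            analog[ix, iy, iz] += e_kev - e_new
        else:
            outside_dep += e_kev - e_new
        if e_new < cutoff_kev:
            if inside:
                analog[ix, iy, iz] += e_new
                kerma[ix, iy, iz] += e_new
            else:
                outside_dep += e_new
            return outside_dep
        phi = 2.0 * np.pi * np.random.random()
        ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
        e_kev = e_new


@njit(cache=True)
def _deposit_positron(x, y, z, t_kev, density, mats, h_cm,
                      rlog_e, rlog_r, positron, analog):
    """Straight-line CSDA slowing down; returns (x, y, z, deposited, ok).

    ``ok`` is False when the positron leaves the grid before stopping.
    Energy deposition per unit areal density is uniform along the track.
    """
    nx, ny, nz = density.shape
    ux, uy, uz = _isotropic()
    range_gcm2 = _interp_loglog(max(t_kev, 10.0), rlog_e, rlog_r)
    remaining = range_gcm2
    deposited = 0.0
    while remaining > 0.0:
        ix = int(np.floor(x / h_cm))
        iy = int(np.floor(y / h_cm))
        iz = int(np.floor(z / h_cm))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            return x, y, z, deposited, False
        rho = density[ix, iy, iz]
        tmax = _INF
        if ux != 0.0:
            tx = ((ix + (1 if ux > 0 else 0)) * h_cm - x) / ux
            if tx < tmax:
                tmax = tx
        if uy != 0.0:
            ty = ((iy + (1 if uy > 0 else 0)) * h_cm - y) / uy
            if ty < tmax:
                tmax = ty
        if uz != 0.0:
            tz = ((iz + (1 if uz > 0 else 0)) * h_cm - z) / uz
            if tz < tmax:
                tmax = tz
        seg = tmax + 1e-9  # nudge across the boundary
        areal = rho * seg
        if areal >= remaining:
            seg = remaining / rho
            areal = remaining
        frac = areal / range_gcm2
        de = t_kev * frac
        positron[ix, iy, iz] += de
        analog[ix, iy, iz] += de
        deposited += de
        x += seg * ux
        y += seg * uy
        z += seg * uz
        remaining -= areal
    return x, y, z, deposited, True


@njit(cache=True)
def _run_batch(density, mats, mu_tbl, pe_tbl, muen_tbl, loge0, dlog,
               h_cm, spec_cdf, spec_e, rlog_e, rlog_r,
               n_hist, seed, src_mode, src_i, src_j, src_k, src_cdf,
               kerma, positron, analog, cutoff_kev,
               infinite_mode, inf_material, inf_rho, kill_radius_cm):
    """One batch of decays; returns (emitted_kev, escaped_kev)."""
    np.random.seed(seed)
    nx, ny, nz = density.shape
    emitted = 0.0
    escaped = 0.0
    for _ in range(n_hist):
        if src_mode == 0:
            iv = src_i
            jv = src_j
            kv = src_k
        else:
            u = np.random.random()
            flat = np.searchsorted(src_cdf, u)
            if flat >= nx * ny * nz:
                flat = nx * ny * nz - 1
            iv = flat // (ny * nz)
            jv = (flat // nz) % ny
            kv = flat % nz
        x = (iv + np.random.random()) * h_cm
        y = (jv + np.random.random()) * h_cm
        z = (kv + np.random.random()) * h_cm

        t_kev = _sample_spectrum(spec_cdf, spec_e)
        emitted += t_kev + 2.0 * ANNIHILATION_KEV
        x, y, z, dep, ok = _deposit_positron(x, y, z, t_kev, density, mats,
                                             h_cm, rlog_e, rlog_r,
                                             positron, analog)
        if not ok:
            escaped += (t_kev - dep) + 2.0 * ANNIHILATION_KEV
            continue
        ux, uy, uz = _isotropic()
        if infinite_mode:
            escaped += _track_photon_infinite(
                x, y, z, ux, uy, uz, ANNIHILATION_KEV, inf_material, inf_rho,
                mu_tbl, pe_tbl, muen_tbl, loge0, dlog, h_cm, nx, ny, nz,
                kerma, analog, cutoff_kev, kill_radius_cm)
            escaped += _track_photon_infinite(
                x, y, z, -ux, -uy, -uz, ANNIHILATION_KEV, inf_material,
                inf_rho, mu_tbl, pe_tbl, muen_tbl, loge0, dlog, h_cm,
                nx, ny, nz, kerma, analog, cutoff_kev, kill_radius_cm)
        else:
            escaped += _track_photon(x, y, z, ux, uy, uz, ANNIHILATION_KEV,
                                     density, mats, mu_tbl, pe_tbl, muen_tbl,
                                     loge0, dlog, h_cm, kerma, analog,
                                     cutoff_kev)
            escaped += _track_photon(x, y, z, -ux, -uy, -uz, ANNIHILATION_KEV,
                                     density, mats, mu_tbl, pe_tbl, muen_tbl,
                                     loge0, dlog, h_cm, kerma, analog,
                                     cutoff_kev)
    return emitted, escaped


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------

@dataclass
class TransportResult:
    """Raw batched tallies from a transport run (energies in keV).

    ``kerma_batches`` holds the photon heating tally, ``positron_batches``
    the positron track deposition, ``analog_batches`` the collision-based
    deposition of both (which conserves energy together with the escape
    tally).
    """

    kerma_batches: np.ndarray    # (n_batches, nx, ny, nz), keV
    positron_batches: np.ndarray
    analog_batches: np.ndarray
    emitted_kev: np.ndarray      # per batch
    escaped_kev: np.ndarray
    histories: int
    n_batches: int
    seed: int

    def _select(self, which: str) -> np.ndarray:
        if which == "kerma":
            return self.kerma_batches + self.positron_batches
        if which == "photon":
            return self.kerma_batches
        if which == "positron":
            return self.positron_batches
        if which == "analog":
            return self.analog_batches
        raise ValueError(f"unknown tally {which!r}")

    def tally_mev_per_cm3(self, voxel_volume_cm3: float,
                          which: str = "kerma") -> np.ndarray:
        """Mean deposition in MeV/cm^3 per decay."""
        total = self._select(which).sum(axis=0) / 1000.0
        return total / (voxel_volume_cm3 * self.histories)

    def batch_tallies_mev_per_cm3(self, voxel_volume_cm3: float,
                                  which: str = "kerma") -> np.ndarray:
        per_batch_hist = self.histories / self.n_batches
        return (self._select(which) / 1000.0
                / (voxel_volume_cm3 * per_batch_hist))

    def relative_uncertainty(self, which: str = "kerma") -> np.ndarray:
        """Per-voxel relative standard error of the mean from batch spread."""
        b = self._select(which)
        nb = b.shape[0]
        if nb < 2:
            raise ValueError("uncertainty needs at least 2 batches")
        mean = b.mean(axis=0)
        sd = b.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = sd / (mean * np.sqrt(nb))
        rel[mean == 0] = np.nan
        return rel


def _prepare(density: Volume, materials: Volume | None,
             xs: CrossSectionTable | None):
    xs = xs or default_cross_sections()
    if materials is None:
        mt = xs.material_table or default_material_table()
        mats = mt.classify_material(density.data).astype(np.uint8)
    else:
        mats = materials.data.astype(np.uint8)
    loge0, dlog, mu, pe, muen = xs.dense_grids()
    dens = np.ascontiguousarray(density.data, dtype=np.float64)
    return dens, np.ascontiguousarray(mats), mu, pe, muen, loge0, dlog


def _run(density: Volume, materials: Volume | None, n_histories: int,
         seed: int, n_batches: int, src_mode: int,
         source_index=None, source_cdf=None,
         xs: CrossSectionTable | None = None,
         boundary: str = "vacuum") -> TransportResult:
    dens, mats, mu, pe, muen, loge0, dlog = _prepare(density, materials, xs)
    h_cm = density.spacing_mm / 10.0
    spec = default_spectrum()
    rlog_e = np.log(_RANGE_E_KEV)
    rlog_r = np.log(_RANGE_G_CM2)
    n_batches = max(1, min(n_batches, n_histories))
    per_batch = n_histories // n_batches
    kerma = np.zeros((n_batches,) + dens.shape)
    positron = np.zeros((n_batches,) + dens.shape)
    analog = np.zeros((n_batches,) + dens.shape)
    emitted = np.zeros(n_batches)
    escaped = np.zeros(n_batches)
    if source_index is None:
        source_index = (0, 0, 0)
    if source_cdf is None:
        source_cdf = np.zeros(1)

    infinite_mode = boundary == "infinite"
    inf_material = 0
    inf_rho = 0.0
    kill_radius_cm = 0.0
    if infinite_mode:
        umats = np.unique(mats)
        if umats.size != 1:
            raise ValueError("infinite boundary requires a homogeneous patch")
        inf_material = int(umats[0])
        inf_rho = float(dens.flat[0])
        xs_tab = xs or default_cross_sections()
        mfp = 1.0 / (xs_tab.mass_coefficient(inf_material, ANNIHILATION_KEV)
                     * inf_rho)
        half_diag = 0.5 * h_cm * float(np.sqrt(sum(n**2 for n in dens.shape)))
        kill_radius_cm = half_diag + 6.0 * mfp
    elif boundary != "vacuum":
        raise ValueError(f"unknown boundary mode {boundary!r}")

    for b in range(n_batches):
        bseed = int((seed * 9973 + 7919 * b + 1) % (2**31 - 1))
        emitted[b], escaped[b] = _run_batch(
            dens, mats, mu, pe, muen, loge0, dlog, h_cm,
            spec.cdf, spec.energies, rlog_e, rlog_r,
            per_batch, bseed, src_mode,
            int(source_index[0]), int(source_index[1]), int(source_index[2]),
            source_cdf, kerma[b], positron[b], analog[b], PHOTON_CUTOFF_KEV,
            infinite_mode, inf_material, inf_rho, kill_radius_cm)
    return TransportResult(kerma, positron, analog, emitted, escaped,
                           per_batch * n_batches, n_batches, seed)


def simulate_kernel(patch: Volume, n_histories: int, seed: int,
                    materials: Volume | None = None, n_batches: int = 10,
                    tally: str = "kerma",
                    xs: CrossSectionTable | None = None,
                    boundary: str = "vacuum",
                    medium: str = "patch") -> VoxelKernel:
    """Voxel S-value kernel for a 64^3 density patch at 3 mm spacing.

    The decay site is uniform within the central source voxel (32, 32, 32).
    Deposition is MeV/cm^3 per decay; the relative-uncertainty grid comes
    from batch statistics.  ``boundary='infinite'`` (homogeneous patches
    only) embeds the mesh in an unbounded medium of the same composition.
    """
    if patch.shape != (KERNEL_SHAPE,) * 3:
        raise ValueError(f"kernel patches must be {KERNEL_SHAPE}^3, "
                         f"got {patch.shape}")
    if abs(patch.spacing_mm - KERNEL_SPACING_MM) > 1e-9:
        raise ValueError("kernel patches must be at 3 mm spacing")
    if n_histories < 1000:
        raise ValueError("need at least 1e3 histories")
    res = _run(patch, materials, n_histories, seed, n_batches,
               src_mode=0, source_index=SOURCE_INDEX, xs=xs,
               boundary=boundary)
    dep = res.tally_mev_per_cm3(patch.voxel_volume_cm3, tally)
    unc = res.relative_uncertainty(tally) if res.n_batches >= 2 else None
    return VoxelKernel(
        deposition=dep, spacing_mm=patch.spacing_mm,
        source_index=SOURCE_INDEX, uncertainty=unc,
        histories=res.histories, seed=seed, medium=medium,
        provenance=f"mc-{tally}-{boundary}",
        batch_sums=res.batch_tallies_mev_per_cm3(patch.voxel_volume_cm3,
                                                 tally),
        positron_deposition=res.tally_mev_per_cm3(patch.voxel_volume_cm3,
                                                  "positron"))


def simulate_point_source(density: Volume, source_index, n_histories: int,
                          seed: int, materials: Volume | None = None,
                          n_batches: int = 10, tally: str = "kerma",
                          xs: CrossSectionTable | None = None):
    """Deposition (MeV/cm^3 per decay) for a delta source in any geometry.

    Like :func:`simulate_kernel` but without the 64^3 shape contract; used
    for toy geometries (reciprocity benchmarks) and as the direct-MC oracle.
    Returns (deposition, TransportResult).
    """
    res = _run(density, materials, n_histories, seed, n_batches,
               src_mode=0, source_index=source_index, xs=xs)
    dep = res.tally_mev_per_cm3(density.voxel_volume_cm3, tally)
    return dep, res


def border_to_center_ratio(kernel: VoxelKernel) -> float:
    """Photon-field deposition ratio: mean of the six face-centre border
    voxels over the source voxel.

    The positron self-dose (a separate tally component) is excluded: the
    ratio characterizes the annihilation-photon heating field whose spatial
    decay motivates the 19.2 cm kernel extent.
    """
    pos = getattr(kernel, "positron_deposition", None)
    dep = kernel.deposition if pos is None else kernel.deposition - pos
    dep = np.clip(dep, 0.0, None)
    n = kernel.shape[0]
    c = kernel.source_index
    borders = [dep[0, c[1], c[2]], dep[n - 1, c[1], c[2]],
               dep[c[0], 0, c[2]], dep[c[0], n - 1, c[2]],
               dep[c[0], c[1], 0], dep[c[0], c[1], n - 1]]
    return float(np.mean(borders) / dep[c])


def estimate_uncertainty(kernel: VoxelKernel, radius_cm: float = 10.0,
                         half_width_cm: float = 0.25) -> float:
    """Mean relative standard error over voxels in a radial shell.

    Uses the kernel's retained batch tallies (error if absent or single
    batch).  Voxels with zero mean deposition are excluded.
    """
    if kernel.batch_sums is None or kernel.batch_sums.shape[0] < 2:
        raise ValueError("kernel lacks batch statistics (need >= 2 batches)")
    b = kernel.batch_sums
    nb = b.shape[0]
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    h = kernel.spacing_mm / 10.0
    idx = np.indices(kernel.shape)
    r = np.sqrt(sum((idx[a] - kernel.source_index[a]) ** 2
                    for a in range(3))) * h
    shell = (np.abs(r - radius_cm) <= half_width_cm) & (mean > 0)
    if not shell.any():
        raise ValueError(f"no voxels in shell at {radius_cm} cm")
    rel = sd[shell] / (mean[shell] * np.sqrt(nb))
    return float(rel.mean())


def simulate_direct_dose(density: Volume, cumulated: Volume,
                         n_histories: int, seed: int,
                         materials: Volume | None = None,
                         n_batches: int = 10, tally: str = "kerma",
                         xs: CrossSectionTable | None = None) -> DoseMap:
    """Direct Monte Carlo whole-body dose map (Gy) - the reference engine.

    Decay sites are sampled proportional to the cumulated-activity map
    (total decays per voxel); the per-history tally is scaled by the total
    number of decays and converted to Gy.
    """
    from .dose import tally_to_gray  # local import; dose does not import us

    density.require_same_grid(cumulated, "density and cumulated activity")
    total_decays = float(cumulated.data.sum())
    if total_decays <= 0:
        warnings.warn("cumulated activity is zero; returning zero dose")
        return DoseMap(np.zeros(density.shape), spacing_mm=density.spacing_mm,
                       engine="direct-mc", params={"histories": 0})
    cdf = np.cumsum(cumulated.data.ravel())
    cdf = cdf / cdf[-1]
    res = _run(density, materials, n_histories, seed, n_batches,
               src_mode=1, source_cdf=cdf, xs=xs)
    per_decay = res.tally_mev_per_cm3(density.voxel_volume_cm3, tally)
    gy = tally_to_gray(per_decay, total_decays, density)
    return DoseMap(gy, spacing_mm=density.spacing_mm, engine="direct-mc",
                   params={"histories": res.histories, "seed": seed,
                           "tally": tally, "total_decays": total_decays})
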