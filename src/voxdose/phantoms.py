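"""Synthetic voxel phantoms and dynamic activity series.

These stand in for whole-body CT and dynamic PET inputs: a torso-like body
ellipsoid of soft tissue containing two lung ellipsoids, a spine with a
cortical shell around a trabecular core, and an optional spherical lesion.
Structures are painted with the precedence lesion > bone > lung > soft
tissue; everything outside the body is air.  Densities are the nominal class
densities plus an optional seeded jitter that is clipped to stay inside the
class's density bin, so the material volume always equals the voxelwise
classification of the density volume.

The activity model is a per-tissue uptake-washout curve

    A(t) = A0 * (1 - exp(-k_u * t)) * exp(-lambda * t)   [Bq/mL]

sampled at 13 frame mid-times spanning 0-90 min by default, with optional
Poisson-like Gaussian noise (variance proportional to the activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .constants import KERNEL_SHAPE, KERNEL_SPACING_MM, SOURCE_INDEX
from .materials import MaterialTable, default_material_table
from .volumes import TimeActivitySeries, Volume, f18_decay_constant

__all__ = [
    "Ellipsoid", "SpineSpec", "LesionSpec", "PhantomSpec", "TissueKinetics",
    "generate_phantom", "generate_activity_series", "extract_patch",
    "default_frame_times", "default_kinetics",
]

AIR, LUNG, ADIPOSE, SOFT_TISSUE, TRANSITIONAL = 0, 1, 2, 3, 4
TRABECULAR_BONE, CORTICAL_BONE = 5, 11  # nominal 1.18 and 1.92 g/cm^3


@dataclass
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def mask(self, shape, spacing_mm) -> np.ndarray:
        grids = np.meshgrid(*[(np.arange(n) + 0.5) * spacing_mm
                              for n in shape], indexing="ij")
        r2 = sum(((g - c) / a) ** 2 for g, c, a in
                 zip(grids, self.center_mm, self.semi_axes_mm))
        return r2 <= 1.0


@dataclass
class SpineSpec:
    """Cylinder along z: cortical shell around a trabecular core."""

    center_xy_mm: tuple[float, float]
    radius_mm: float = 12.0
    shell_mm: float = 3.0
    z_range_mm: tuple[float, float] | None = None


@dataclass
class LesionSpec:
    center_mm: tuple[float, float, float]
    radius_mm: float = 9.0
    material: int = SOFT_TISSUE


@dataclass
class PhantomSpec:
    """Geometry of the synthetic torso phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = KERNEL_SPACING_MM
    body: Ellipsoid | None = None
    lungs: list[Ellipsoid] = field(default_factory=list)
    spine: SpineSpec | None = None
    lesion: LesionSpec | None = None
    body_material: int = SOFT_TISSUE
    density_noise_sigma: float = 0.01

    @classmethod
    def default_torso(cls, shape=(64, 64, 64), spacing_mm=KERNEL_SPACING_MM,
                      lesion: LesionSpec | None = None) -> "PhantomSpec":
        ext = [n * spacing_mm for n in shape]
        cx, cy, cz = [e / 2 for e in ext]
        body = Ellipsoid((cx, cy, cz),
                         (0.46 * ext[0], 0.40 * ext[1], 0.52 * ext[2]))
        lungs = [
            Ellipsoid((cx - 0.20 * ext[0], cy - 0.06 * ext[1], cz),
                      (0.14 * ext[0], 0.18 * ext[1], 0.32 * ext[2])),
            Ellipsoid((cx + 0.20 * ext[0], cy - 0.06 * ext[1], cz),
                      (0.14 * ext[0], 0.18 * ext[1], 0.32 * ext[2])),
        ]
        spine = SpineSpec((cx, cy + 0.26 * ext[1]),
                          radius_mm=0.07 * ext[0], shell_mm=spacing_mm)
        return cls(shape=tuple(shape), spacing_mm=spacing_mm, body=body,
                   lungs=lungs, spine=spine, lesion=lesion)

    @classmethod
    def empty(cls, shape=(32, 32, 32), spacing_mm=KERNEL_SPACING_MM):
        return cls(shape=tuple(shape), spacing_mm=spacing_mm, body=None)

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self) -> str:
        def enc(o):
            if o is None:
                return None
            if isinstance(o, Ellipsoid):
                return {"center_mm": list(o.center_mm),
                        "semi_axes_mm": list(o.semi_axes_mm)}
            if isinstance(o, SpineSpec):
                return {"center_xy_mm": list(o.center_xy_mm),
                        "radius_mm": o.radius_mm, "shell_mm": o.shell_mm,
                        "z_range_mm": list(o.z_range_mm) if o.z_range_mm else None}
            if isinstance(o, LesionSpec):
                return {"center_mm": list(o.center_mm),
                        "radius_mm": o.radius_mm, "material": o.material}
            return o
        doc = {"shape": list(self.shape), "spacing_mm": self.spacing_mm,
               "body": enc(self.body), "lungs": [enc(l) for l in self.lungs],
               "spine": enc(self.spine), "lesion": enc(self.lesion),
               "body_material": self.body_material,
               "density_noise_sigma": self.density_noise_sigma}
        return yaml.safe_dump(doc)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        doc = yaml.safe_load(text)

        def ell(d):
            return None if d is None else Ellipsoid(tuple(d["center_mm"]),
                                                    tuple(d["semi_axes_mm"]))
        spine = doc.get("spine")
        lesion = doc.get("lesion")
        return cls(
            shape=tuple(doc["shape"]), spacing_mm=doc["spacing_mm"],
            body=ell(doc.get("body")),
            lungs=[ell(l) for l in doc.get("lungs", [])],
            spine=None if spine is None else SpineSpec(
                tuple(spine["center_xy_mm"]), spine["radius_mm"],
                spine["shell_mm"],
                tuple(spine["z_range_mm"]) if spine.get("z_range_mm") else None),
            lesion=None if lesion is None else LesionSpec(
                tuple(lesion["center_mm"]), lesion["radius_mm"],
                lesion["material"]),
            body_material=doc.get("body_material", SOFT_TISSUE),
            density_noise_sigma=doc.get("density_noise_sigma", 0.01),
        )


def _spine_masks(spec: SpineSpec, shape, spacing_mm):
    x = (np.arange(shape[0]) + 0.5) * spacing_mm
    y = (np.arange(shape[1]) + 0.5) * spacing_mm
    z = (np.arange(shape[2]) + 0.5) * spacing_mm
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx - spec.center_xy_mm[0], yy - spec.center_xy_mm[1])
    outer2d = r <= spec.radius_mm
    inner2d = r <= max(spec.radius_mm - spec.shell_mm, 0.0)
    zmask = np.ones(shape[2], dtype=bool)
    if spec.z_range_mm is not None:
        zmask = (z >= spec.z_range_mm[0]) & (z <= spec.z_range_mm[1])
    outer = outer2d[:, :, None] & zmask[None, None, :]
    inner = inner2d[:, :, None] & zmask[None, None, :]
    return outer & ~inner, inner


def _density_bounds(table: MaterialTable):
    """Per-class density interval [low, high) with safety margins."""
    edges = table.density_edges
    lows = np.concatenate([[1e-5], edges])
    highs = np.concatenate([edges, [3.5]])
    return lows, highs


def generate_phantom(spec: PhantomSpec, seed: int = 0,
                     table: MaterialTable | None = None):
    """Build (DensityVolume, MaterialVolume) from a phantom spec.

    Deterministic for a fixed seed.  The material volume equals the
    voxelwise classification of the density volume by construction.
    """
    table = table or default_material_table()
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)

    materials = np.full(shape, AIR, dtype=np.int8)
    if spec.body is not None:
        body = spec.body.mask(shape, spec.spacing_mm)
        materials[body] = spec.body_material
        for lung in spec.lungs:
            materials[lung.mask(shape, spec.spacing_mm) & body] = LUNG
        if spec.spine is not None:
            shell, core = _spine_masks(spec.spine, shape, spec.spacing_mm)
            materials[shell & body] = CORTICAL_BONE
            materials[core & body] = TRABECULAR_BONE
        if spec.lesion is not None:
            les = Ellipsoid(spec.lesion.center_mm,
                            (spec.lesion.radius_mm,) * 3)
            materials[les.mask(shape, spec.spacing_mm) & body] = \
                spec.lesion.material

    density = table.densities[materials].astype(float)
    if spec.density_noise_sigma > 0:
        lows, highs = _density_bounds(table)
        jitter = rng.normal(0.0, spec.density_noise_sigma, size=shape)
        jitter[materials == AIR] = 0.0  # air density left nominal
        density = density + jitter
        density = np.clip(density, lows[materials] + 1e-6,
                          highs[materials] - 1e-6)

    dv = Volume(density, spacing_mm=spec.spacing_mm)
    mv = Volume(materials, spacing_mm=spec.spacing_mm)
    return dv, mv


# ---------------------------------------------------------------------------
# Dynamic activity
# ---------------------------------------------------------------------------

@dataclass
class TissueKinetics:
    """Uptake-washout parameters: A(t) = a0*(1-exp(-k_u t))*exp(-lambda t)."""

    a0_bq_ml: float
    uptake_rate_per_min: float = 0.15

    def __post_init__(self):
        if self.a0_bq_ml < 0 or self.uptake_rate_per_min < 0:
            raise ValueError("kinetic parameters must be nonnegative")

    def activity(self, t_min, decay_constant_per_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return (self.a0_bq_ml * (1.0 - np.exp(-self.uptake_rate_per_min * t))
                * np.exp(-decay_constant_per_min * t))


def default_frame_times() -> np.ndarray:
    """13 frame mid-times (min) at ever-increasing intervals over 0-90 min."""
    return np.array([0.75, 2.0, 3.5, 5.5, 8.0, 11.5, 16.0, 22.0, 30.0,
                     40.0, 53.0, 69.0, 88.0])


def default_kinetics() -> dict[int, TissueKinetics]:
    """FDG-like uptake levels per tissue class (Bq/mL at plateau)."""
    kin = {
        LUNG: TissueKinetics(1200.0, 0.25),
        ADIPOSE: TissueKinetics(800.0, 0.10),
        SOFT_TISSUE: TissueKinetics(5000.0, 0.15),
        TRANSITIONAL: TissueKinetics(3000.0, 0.15),
    }
    for mid in range(TRABECULAR_BONE, 13):
        kin[mid] = TissueKinetics(1800.0, 0.12)
    return kin


def generate_activity_series(materials: Volume,
                             kinetics: dict[int, TissueKinetics] | None = None,
                             frame_times_min=None,
                             seed: int = 0,
                             noise_scale_bq_ml: float = 0.0,
                             lesion_mask: np.ndarray | None = None,
                             lesion_kinetics: TissueKinetics | None = None,
                             decay_constant_per_min: float | None = None
                             ) -> TimeActivitySeries:
    """Dynamic activity frames for a material phantom.

    Air voxels carry zero activity.  With ``noise_scale_bq_ml > 0``,
    Gaussian noise of variance ``noise_scale_bq_ml * A`` is added (clipped
    at zero), seeded and reproducible.
    """
    kinetics = default_kinetics() if kinetics is None else kinetics
    times = (default_frame_times() if frame_times_min is None
             else np.asarray(frame_times_min, dtype=float))
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    lam = (f18_decay_constant() if decay_constant_per_min is None
           else float(decay_constant_per_min))
    mats = materials.data.astype(int)
    rng = np.random.default_rng(seed)

    frames = np.zeros((times.size,) + mats.shape)
    for mid, kin in kinetics.items():
        mask = mats == mid
        if mid == AIR or not mask.any():
            continue
        frames[:, mask] = kin.activity(times, lam)[:, None]
    if lesion_mask is not None and lesion_kinetics is not None:
        frames[:, lesion_mask] = lesion_kinetics.activity(times, lam)[:, None]

    if noise_scale_bq_ml > 0:
        noise = rng.normal(size=frames.shape) * np.sqrt(
            noise_scale_bq_ml * frames)
        frames = np.clip(frames + noise, 0.0, None)
    frames[:, mats == AIR] = 0.0

    return TimeActivitySeries(times_min=times, frames=frames,
                              spacing_mm=materials.spacing_mm,
                              decay_constant_per_min=lam)


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def extract_patch(volume: Volume, center: tuple[int, int, int],
                  size: int = KERNEL_SHAPE, pad_value: float | None = None,
                  resample: bool = False) -> Volume:
    """Extract a ``size^3`` patch with the given voxel at the kernel source index.

    Regions outside the volume are padded (air density by default).  The
    volume must be at the 3 mm kernel spacing; other spacings are resampled
    first when ``resample=True`` and rejected otherwise.
    """
    if abs(volume.spacing_mm - KERNEL_SPACING_MM) > 1e-9:
        if not resample:
            raise ValueError(
                f"patch extraction requires {KERNEL_SPACING_MM} mm spacing; "
                f"got {volume.spacing_mm} mm (pass resample=True)")
        zoom = volume.spacing_mm / KERNEL_SPACING_MM
        data = ndimage.zoom(volume.data.astype(float), zoom, order=1)
        center = tuple(int(round(c * zoom)) for c in center)
        volume = Volume(data, spacing_mm=KERNEL_SPACING_MM,
                        origin_mm=volume.origin_mm)
    cx, cy, cz = (int(c) for c in center)
    if not all(0 <= c < n for c, n in zip((cx, cy, cz), volume.shape)):
        raise ValueError(f"center {center} outside volume {volume.shape}")
    if pad_value is None:
        pad_value = 0.00121 if np.issubdtype(volume.data.dtype,
                                             np.floating) else 0
    src = size // 2  # = SOURCE_INDEX for the 64^3 kernel grid
    patch = np.full((size, size, size), pad_value, dtype=volume.data.dtype)
    lo = [c - src for c in (cx, cy, cz)]
    src_lo = [max(0, l) for l in lo]
    src_hi = [min(n, l + size) for l, n in zip(lo, volume.shape)]
    dst_lo = [sl - l for sl, l in zip(src_lo, lo)]
    dst_hi = [dl + (sh - sl) for dl, sl, sh in zip(dst_lo, src_lo, src_hi)]
    patch[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        volume.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1],
                    src_lo[2]:src_hi[2]]
    return Volume(patch, spacing_mm=KERNEL_SPACING_MM)
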