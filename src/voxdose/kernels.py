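"""Kernel providers: a uniform contract mapping a density patch to a kernel.

Four backends implement ``kernel_for(patch)``:

* ``SSVProvider``     - one homogeneous soft-tissue kernel for every patch;
* ``MSVProvider``     - the homogeneous kernel of the patch's central-voxel
                        medium, from a small per-medium library;
* ``OracleProvider``  - Monte Carlo simulation of the actual patch, cached
                        by a content hash of the quantized material patch;
* learned             - see :class:`voxdose.nn.LearnedKernelProvider`.

Also here: the reciprocity correction, which rescales a kernel voxelwise by
the target-to-source mass energy-absorption coefficient ratio at 511 keV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import KERNEL_SHAPE, KERNEL_SPACING_MM, SOURCE_INDEX
from .cross_sections import CrossSectionTable, default_cross_sections
from .materials import MaterialTable, default_material_table
from .phantoms import LUNG, SOFT_TISSUE, TRABECULAR_BONE, CORTICAL_BONE
from .transport import simulate_kernel
from .volumes import Volume, VoxelKernel

__all__ = [
    "KernelLibrary", "KernelProvider", "SSVProvider", "MSVProvider",
    "OracleProvider", "build_homogeneous_kernel", "build_ssv_kernel",
    "build_msv_library", "get_specific_kernel", "apply_reciprocity_correction",
    "material_patch_hash", "MSV_MEDIA",
]

MSV_MEDIA = (SOFT_TISSUE, LUNG, TRABECULAR_BONE, CORTICAL_BONE)


def homogeneous_patch(material_id: int,
                      table: MaterialTable | None = None) -> Volume:
    table = table or default_material_table()
    rho = table.material(material_id).density
    return Volume(np.full((KERNEL_SHAPE,) * 3, rho),
                  spacing_mm=KERNEL_SPACING_MM)


def build_homogeneous_kernel(material_id: int, n_histories: int, seed: int,
                             table: MaterialTable | None = None,
                             boundary: str = "infinite",
                             **kwargs) -> VoxelKernel:
    """Homogeneous-medium 64^3 kernel for one material class.

    By definition the SSV/MSV kernels describe an infinite homogeneous
    medium tallied on the finite 64^3 mesh, hence the default boundary.
    """
    table = table or default_material_table()
    patch = homogeneous_patch(material_id, table)
    mats = Volume(np.full(patch.shape, material_id, dtype=np.uint8),
                  spacing_mm=patch.spacing_mm)
    return simulate_kernel(patch, n_histories, seed, materials=mats,
                           boundary=boundary,
                           medium=table.material(material_id).name, **kwargs)


def build_ssv_kernel(n_histories: int, seed: int, **kwargs) -> VoxelKernel:
    """The single (soft-tissue) voxel S-value kernel."""
    return build_homogeneous_kernel(SOFT_TISSUE, n_histories, seed, **kwargs)


@dataclass
class KernelLibrary:
    """Map material id -> homogeneous kernel, with build provenance."""

    kernels: dict[int, VoxelKernel]
    histories: int = 0
    seed: int | None = None

    def __post_init__(self):
        kerns = list(self.kernels.values())
        for k in kerns[1:]:
            if (k.shape != kerns[0].shape
                    or abs(k.spacing_mm - kerns[0].spacing_mm) > 1e-9
                    or k.source_index != kerns[0].source_index):
                raise ValueError("library kernels must share geometry")

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["histories"] = self.histories
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            for mid, k in self.kernels.items():
                g = f.create_group(f"medium_{mid}")
                _write_kernel(g, k)

    @classmethod
    def load(cls, path) -> "KernelLibrary":
        kernels = {}
        with h5py.File(path, "r") as f:
            for name in f:
                mid = int(name.split("_")[1])
                kernels[mid] = _read_kernel(f[name])
            seed = int(f.attrs.get("seed", -1))
            return cls(kernels, histories=int(f.attrs.get("histories", 0)),
                       seed=None if seed < 0 else seed)


def _write_kernel(g, k: VoxelKernel):
    g.create_dataset("deposition", data=k.deposition)
    if k.uncertainty is not None:
        g.create_dataset("uncertainty", data=k.uncertainty)
    if k.batch_sums is not None:
        g.create_dataset("batch_sums", data=k.batch_sums)
    if k.positron_deposition is not None:
        g.create_dataset("positron_deposition", data=k.positron_deposition)
    g.attrs["spacing_mm"] = k.spacing_mm
    g.attrs["source_index"] = k.source_index
    g.attrs["histories"] = k.histories
    g.attrs["seed"] = -1 if k.seed is None else k.seed
    g.attrs["medium"] = k.medium
    g.attrs["provenance"] = k.provenance


def _read_kernel(g) -> VoxelKernel:
    seed = int(g.attrs["seed"])
    return VoxelKernel(
        deposition=g["deposition"][()],
        spacing_mm=float(g.attrs["spacing_mm"]),
        source_index=tuple(int(v) for v in g.attrs["source_index"]),
        uncertainty=g["uncertainty"][()] if "uncertainty" in g else None,
        batch_sums=g["batch_sums"][()] if "batch_sums" in g else None,
        positron_deposition=(g["positron_deposition"][()]
                             if "positron_deposition" in g else None),
        histories=int(g.attrs["histories"]),
        seed=None if seed < 0 else seed,
        medium=str(g.attrs["medium"]),
        provenance=str(g.attrs["provenance"]),
    )


def save_kernel(kernel: VoxelKernel, path):
    with h5py.File(path, "w") as f:
        _write_kernel(f, kernel)


def load_kernel(path) -> VoxelKernel:
    with h5py.File(path, "r") as f:
        return _read_kernel(f)


def build_msv_library(media=MSV_MEDIA, n_histories: int = 100_000,
                      seed: int = 0, **kwargs) -> KernelLibrary:
    """One homogeneous kernel per medium (soft tissue, lung, two bones)."""
    kernels = {int(m): build_homogeneous_kernel(int(m), n_histories,
                                                seed + i, **kwargs)
               for i, m in enumerate(media)}
    return KernelLibrary(kernels, histories=n_histories, seed=seed)


def material_patch_hash(material_patch: np.ndarray) -> str:
    """Content hash of a quantized material patch (cache key)."""
    arr = np.ascontiguousarray(material_patch, dtype=np.uint8)
    return hashlib.sha1(arr.tobytes()).hexdigest()


class KernelProvider:
    """Contract: ``kernel_for(density_patch) -> VoxelKernel``, deterministic."""

    mode = "abstract"
    needs_reciprocity_correction = False

    def kernel_for(self, patch: Volume) -> VoxelKernel:
        raise NotImplementedError


@dataclass
class SSVProvider(KernelProvider):
    kernel: VoxelKernel
    mode = "ssv"

    def kernel_for(self, patch: Volume) -> VoxelKernel:
        return self.kernel


@dataclass
class MSVProvider(KernelProvider):
    library: KernelLibrary
    table: MaterialTable | None = None
    mode = "msv"

    def kernel_for(self, patch: Volume) -> VoxelKernel:
        table = self.table or default_material_table()
        centre = patch.data[tuple(s for s in SOURCE_INDEX)]
        cls = int(table.classify_material(float(centre)))
        media = sorted(self.library.kernels)
        dens = np.array([table.material(m).density for m in media])
        target = table.material(cls).density
        return self.library.kernels[media[int(np.argmin(np.abs(dens - target)))]]


@dataclass
class OracleProvider(KernelProvider):
    """Monte Carlo on the actual patch; cached by material-patch hash."""

    n_histories: int = 20_000
    seed: int = 0
    n_batches: int = 2
    table: MaterialTable | None = None
    cache_path: str | None = None
    _cache: dict = field(default_factory=dict, repr=False)
    mode = "oracle"

    def kernel_for(self, patch: Volume) -> VoxelKernel:
        table = self.table or default_material_table()
        mats = table.classify_material(patch.data).astype(np.uint8)
        key = material_patch_hash(mats)
        if key in self._cache:
            return self._cache[key]
        if self.cache_path is not None:
            import os
            if os.path.exists(self.cache_path):
                with h5py.File(self.cache_path, "r") as f:
                    if key in f:
                        k = _read_kernel(f[key])
                        self._cache[key] = k
                        return k
        kernel = simulate_kernel(patch, self.n_histories, self.seed,
                                 materials=Volume(mats, patch.spacing_mm),
                                 n_batches=self.n_batches,
                                 medium=f"patch:{key[:12]}")
        kernel.batch_sums = None  # keep the cache lean
        self._cache[key] = kernel
        if self.cache_path is not None:
            with h5py.File(self.cache_path, "a") as f:
                if key not in f:
                    _write_kernel(f.create_group(key), kernel)
        return kernel


def get_specific_kernel(provider: KernelProvider, patch: Volume) -> VoxelKernel:
    """Fetch the specific S-value kernel of a density patch from any backend."""
    return provider.kernel_for(patch)


def apply_reciprocity_correction(kernel: VoxelKernel, source_material: int,
                                 patch_materials: np.ndarray,
                                 energy_kev: float = 511.0,
                                 xs: CrossSectionTable | None = None
                                 ) -> VoxelKernel:
    """Voxelwise multiplication by (mu_en/rho)_target / (mu_en/rho)_source.

    The reciprocity extension to heterogeneous media: deposition scales with
    the local mass energy-absorption coefficient, evaluated at the
    annihilation-photon energy.
    """
    xs = xs or default_cross_sections()
    mats = np.asarray(patch_materials, dtype=int)
    if mats.shape != kernel.shape:
        raise ValueError("material patch and kernel shapes differ")
    n_mat = len(xs.material_table)
    muen = np.array([xs.mass_coefficient(m, energy_kev, "muen")
                     for m in range(n_mat)])
    ratio = muen[mats] / muen[int(source_material)]
    out = kernel.copy()
    out.deposition = kernel.deposition * ratio
    out.uncertainty = kernel.uncertainty
    out.provenance = kernel.provenance + "+reciprocity"
    out.batch_sums = None
    return out


def reciprocity_benchmark(n_histories: int = 1_000_000, seed: int = 11,
                          xs: CrossSectionTable | None = None) -> dict:
    """Validate the reciprocity extension on a three-media toy geometry.

    A 32^3 grid at 3 mm holds a junction of soft tissue, lung and cortical
    bone.  For each pair of nearby source/target voxels straddling the
    interfaces, the per-mass deposition at the target is simulated directly
    and predicted from the source/target-interchanged simulation times the
    target-to-source mass energy-absorption coefficient ratio at 511 keV.
    Mirror symmetry of the geometry in z is used to average the paired
    voxel tallies and suppress statistical noise.

    Returns per-pair relative differences (%) and their maximum magnitude.
    """
    from .transport import simulate_point_source

    xs = xs or default_cross_sections()
    mt = xs.material_table or default_material_table()
    n = 32
    mats = np.full((n, n, n), SOFT_TISSUE, dtype=np.uint8)
    mats[:16, 16:, :] = LUNG
    mats[16:, 16:, :] = CORTICAL_BONE
    dens = mt.densities[mats]
    dv = Volume(dens, KERNEL_SPACING_MM)
    mv = Volume(mats, KERNEL_SPACING_MM)
    points = {"soft_tissue": (14, 13, 16), "lung": (12, 18, 16),
              "cortical_bone": (19, 17, 16)}

    deps = {}
    for i, (name, p) in enumerate(points.items()):
        dep, _ = simulate_point_source(dv, p, n_histories, seed=seed + i,
                                       materials=mv, n_batches=2, xs=xs)
        deps[name] = dep

    def dose_per_mass(dep, p):
        x, y, z = p
        return 0.5 * (dep[x, y, z] + dep[x, y, n - 1 - z]) / dens[x, y, z]

    diffs = {}
    for a, b in [("soft_tissue", "cortical_bone"), ("soft_tissue", "lung"),
                 ("lung", "cortical_bone")]:
        pa, pb = points[a], points[b]
        direct = dose_per_mass(deps[a], pb)
        swapped = dose_per_mass(deps[b], pa)
        recip = swapped * xs.energy_absorption_ratio(int(mats[pb]),
                                                     int(mats[pa]))
        diffs[f"{a}->{b}"] = 100.0 * (recip - direct) / direct
    return {"pair_differences_pct": diffs,
            "max_abs_difference_pct": max(abs(v) for v in diffs.values()),
            "histories_per_run": n_histories, "seed": seed}
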