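"""In-memory containers shared across modules: volumes, kernels, time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (KERNEL_SHAPE, KERNEL_SPACING_MM, SOURCE_INDEX,
                        F18_HALF_LIFE_MIN)

__all__ = ["Volume", "VoxelKernel", "TimeActivitySeries", "DoseMap",
           "f18_decay_constant"]


def f18_decay_constant() -> float:
    """F-18 physical decay constant (1/min)."""
    return float(np.log(2.0) / F18_HALF_LIFE_MIN)


@dataclass
class Volume:
    """A 3D scalar grid with isotropic spacing (mm) and origin (mm).

    Used for density maps (g/cm^3), material-id maps, activity frames
    (Bq/mL) and cumulated-activity maps (decays per voxel).
    """

    data: np.ndarray
    spacing_mm: float = KERNEL_SPACING_MM
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume expects a 3D array")
        self.spacing_mm = float(self.spacing_mm)
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.spacing_mm / 10.0) ** 3

    def same_grid_as(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.spacing_mm - other.spacing_mm) <= tol)

    def require_same_grid(self, other: "Volume", what: str = "volumes"):
        if not self.same_grid_as(other):
            raise ValueError(f"{what} are not on the same grid: "
                             f"{self.shape}@{self.spacing_mm}mm vs "
                             f"{other.shape}@{other.spacing_mm}mm")

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


@dataclass
class VoxelKernel:
    """Voxel S-value kernel: energy deposited per decay around a central source.

    ``deposition`` is MeV/cm^3 per decay on a 64^3 grid at 3 mm spacing with
    the source voxel at 0-based index (32, 32, 32).  ``uncertainty`` is the
    per-voxel relative standard error estimated from batch statistics (NaN
    where the mean is zero).  ``batch_sums`` retains the per-batch deposition
    grids when available, enabling re-estimation of uncertainties.
    """

    deposition: np.ndarray
    spacing_mm: float = KERNEL_SPACING_MM
    source_index: tuple[int, int, int] = SOURCE_INDEX
    uncertainty: np.ndarray | None = None
    histories: int = 0
    seed: int | None = None
    medium: str = "unknown"
    provenance: str = "mc"
    batch_sums: np.ndarray | None = field(default=None, repr=False)
    positron_deposition: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.deposition = np.asarray(self.deposition, dtype=float)
        if self.deposition.ndim != 3:
            raise ValueError("kernel deposition must be a 3D array")
        if np.any(self.deposition < 0):
            raise ValueError("kernel deposition must be nonnegative")

    @property
    def shape(self):
        return self.deposition.shape

    @property
    def extent_cm(self) -> float:
        return self.shape[0] * self.spacing_mm / 10.0

    def total_energy_mev(self) -> float:
        """Total deposited energy per decay (MeV), summing tally * voxel volume."""
        return float(self.deposition.sum() * (self.spacing_mm / 10.0) ** 3)

    def copy(self) -> "VoxelKernel":
        return replace(
            self,
            deposition=self.deposition.copy(),
            uncertainty=None if self.uncertainty is None
            else self.uncertainty.copy(),
            batch_sums=None if self.batch_sums is None
            else self.batch_sums.copy(),
            positron_deposition=None if self.positron_deposition is None
            else self.positron_deposition.copy(),
        )


@dataclass
class TimeActivitySeries:
    """Dynamic per-voxel activity concentration frames (Bq/mL).

    ``times_min`` are frame mid-times in minutes (strictly increasing);
    ``frames`` is (n_frames, nx, ny, nz).
    """

    times_min: np.ndarray
    frames: np.ndarray
    spacing_mm: float = KERNEL_SPACING_MM
    decay_constant_per_min: float = field(default_factory=f18_decay_constant)

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be (n_frames, nx, ny, nz)")
        if self.times_min.shape[0] != self.frames.shape[0]:
            raise ValueError("one mid-time per frame required")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("activities must be nonnegative")
        if self.decay_constant_per_min <= 0:
            raise ValueError("decay constant must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self):
        return self.frames.shape[1:]


@dataclass
class DoseMap(Volume):
    """Absorbed dose in Gy, with the provenance of the producing engine."""

    engine: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.data < 0):
            raise ValueError("dose must be nonnegative")


def default_kernel_grid() -> tuple[int, float]:
    return KERNEL_SHAPE, KERNEL_SPACING_MM
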