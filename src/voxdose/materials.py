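"""Tissue material model: HU -> mass density calibration and 13-class segmentation.

The calibration is a Schneider-style piecewise-linear mapping from CT numbers
to mass density, followed by binning into 13 discrete tissue classes: air,
lung, fat (adipose), soft tissue, one transitional class, and eight bone bins
of increasing mineral content.  Class densities are strictly increasing with
the class index and bin edges are half-open ``[low, high)`` (a density exactly
on an edge maps to the higher class).

The table ships as a versioned JSON data file (``data/materials.json``) so an
alternative calibration can be swapped in via :func:`load_material_table`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "Material",
    "MaterialTable",
    "load_material_table",
    "default_material_table",
    "hu_to_density",
    "classify_material",
    "ELEMENTS",
]

# Z and A for the elements appearing in tissue compositions.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "Ar": (18, 39.948),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
}

HU_MIN, HU_MAX = -1024.0, 3000.0


@dataclass(frozen=True)
class Material:
    """One discrete tissue class.

    Attributes
    ----------
    id : int
        Class index, 0 (air) .. 12 (densest bone bin).
    name : str
        Human-readable label.
    density : float
        Nominal mass density in g/cm^3.
    composition : dict
        Element mass fractions, summing to 1.
    """

    id: int
    name: str
    density: float
    composition: dict[str, float]

    def electrons_per_gram(self) -> float:
        na = 6.02214076e23
        return na * sum(w * ELEMENTS[el][0] / ELEMENTS[el][1]
                        for el, w in self.composition.items())


class MaterialTable:
    """The 13-material calibration: HU mapping, density bins, compositions."""

    def __init__(self, materials: list[Material],
                 hu_breakpoints: list[tuple[float, float]],
                 density_edges: list[float]):
        if len(density_edges) != len(materials) - 1:
            raise ValueError("need one fewer density edge than materials")
        dens = [m.density for m in materials]
        if any(b <= a for a, b in zip(dens, dens[1:])):
            raise ValueError("material densities must be strictly increasing")
        for m in materials:
            s = sum(m.composition.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"mass fractions of {m.name} sum to {s}")
        self.materials = materials
        self.hu_breakpoints = hu_breakpoints
        self.density_edges = np.asarray(density_edges, dtype=float)
        self._hu = np.array([p[0] for p in hu_breakpoints], dtype=float)
        self._rho = np.array([p[1] for p in hu_breakpoints], dtype=float)
        if np.any(np.diff(self._hu) <= 0) or np.any(np.diff(self._rho) < 0):
            raise ValueError("HU calibration must be monotone")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.materials)

    def material(self, material_id: int) -> Material:
        return self.materials[int(material_id)]

    def by_name(self, name: str) -> Material:
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def densities(self) -> np.ndarray:
        return np.array([m.density for m in self.materials])

    # ------------------------------------------------------------------
    def hu_to_density(self, hu):
        """Piecewise-linear, monotone HU -> mass density (g/cm^3).

        Values outside [-1024, 3000] are clamped with a warning.
        """
        hu = np.asarray(hu, dtype=float)
        if np.any(hu < HU_MIN) or np.any(hu > HU_MAX):
            warnings.warn("HU values outside [-1024, 3000] clamped",
                          stacklevel=2)
            hu = np.clip(hu, HU_MIN, HU_MAX)
        out = np.interp(hu, self._hu, self._rho)
        return out if out.ndim else float(out)

    def classify_material(self, density):
        """Map mass density to a class id (total, half-open bins)."""
        density = np.asarray(density, dtype=float)
        out = np.searchsorted(self.density_edges, density, side="right")
        return out.astype(np.int64) if out.ndim else int(out)

    def material_of_hu(self, hu):
        return self.classify_material(self.hu_to_density(hu))


def _interp_composition(soft: dict, bone: dict, t: float) -> dict:
    t = min(max(t, 0.0), 1.0)
    els = sorted(set(soft) | set(bone))
    comp = {el: (1 - t) * soft.get(el, 0.0) + t * bone.get(el, 0.0)
            for el in els}
    total = sum(comp.values())
    return {el: w / total for el, w in comp.items() if w > 0}


def load_material_table(path=None) -> MaterialTable:
    """Load a material table from JSON (the packaged default when path=None)."""
    if path is None:
        ref = resources.files("voxdose.data").joinpath("materials.json")
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    mats = [Material(id=m["id"], name=m["name"], density=m["density"],
                     composition=m["composition"])
            for m in raw["materials"]]
    return MaterialTable(mats,
                         [tuple(p) for p in raw["hu_breakpoints"]],
                         raw["density_edges"])


_DEFAULT: MaterialTable | None = None


def default_material_table() -> MaterialTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_material_table()
    return _DEFAULT


def hu_to_density(hu):
    return default_material_table().hu_to_density(hu)


def classify_material(density):
    return default_material_table().classify_material(density)


# ---------------------------------------------------------------------------
# Construction of the packaged default table (used by scripts/build_data.py
# and by the regeneration test; the package itself loads the JSON file).
# ---------------------------------------------------------------------------

_AIR = {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827}
_LUNG = {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
         "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}
_ADIPOSE = {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
            "S": 0.001, "Cl": 0.001}
_SOFT = {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
         "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}
_CORTICAL = {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
             "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}

# Nominal densities of the 8 bone bins (trabecular ~1.18 .. dense cortical).
_BONE_DENSITIES = [1.18, 1.28, 1.40, 1.53, 1.66, 1.79, 1.92, 2.10]

# Piecewise-linear HU -> density calibration (breakpoint, density) pairs.
_HU_BREAKPOINTS = [(-1024.0, 0.00121), (-1000.0, 0.00121), (-100.0, 0.93),
                   (0.0, 1.00), (100.0, 1.14), (1600.0, 2.00),
                   (3000.0, 2.80)]


def build_default_table() -> MaterialTable:
    """Construct the reference 13-material calibration programmatically."""
    mats = [
        Material(0, "air", 0.00121, _AIR),
        Material(1, "lung", 0.26, _LUNG),
        Material(2, "adipose", 0.95, _ADIPOSE),
        Material(3, "soft_tissue", 1.04, _SOFT),
        Material(4, "transitional", 1.10,
                 _interp_composition(_SOFT, _CORTICAL, (1.10 - 1.04) / 0.88)),
    ]
    for k, rho in enumerate(_BONE_DENSITIES):
        t = (rho - 1.04) / (1.92 - 1.04)
        mats.append(Material(5 + k, f"bone_{k + 1}", rho,
                             _interp_composition(_SOFT, _CORTICAL, t)))
    dens = [m.density for m in mats]
    edges = [0.05, 0.60] + [0.5 * (a + b) for a, b in zip(dens[2:], dens[3:])]
    return MaterialTable(mats, _HU_BREAKPOINTS, edges)


def table_to_json(table: MaterialTable) -> dict:
    return {
        "version": 1,
        "materials": [
            {"id": m.id, "name": m.name, "density": m.density,
             "composition": m.composition}
            for m in table.materials
        ],
        "hu_breakpoints": [list(p) for p in table.hu_breakpoints],
        "density_edges": list(table.density_edges),
    }
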