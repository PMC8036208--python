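"""Photon cross-section and energy-absorption tables for the 13 tissue classes.

The model keeps exactly the two interaction channels the transport engine
uses at annihilation-photon energies:

* incoherent (Compton) scattering on free electrons, with the analytic
  Klein-Nishina total and energy-transfer cross sections, and
* photoelectric absorption, via a per-element parametrization
  ``tau/rho = K * sum_i w_i Z_i^4.5 / A_i * E^-3.2`` anchored to the
  mass energy-absorption coefficient of water at 10 keV.

Coherent (Rayleigh) scattering and pair production are omitted: the former
redirects but does not absorb energy, the latter is impossible below
1022 keV.  The mass energy-absorption coefficient is the photoelectric part
(assumed locally absorbed) plus the Klein-Nishina energy-transfer part;
radiative losses are negligible in tissue below 1 MeV.

The packaged table (``data/cross_sections.csv``) holds 40 log-spaced nodes
over 10-1000 keV per material; lookups between nodes use log-log
interpolation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .materials import ELEMENTS, Material, MaterialTable, default_material_table

__all__ = [
    "klein_nishina_total",
    "klein_nishina_scatter",
    "klein_nishina_transfer",
    "CrossSectionTable",
    "build_cross_section_table",
    "default_cross_sections",
    "attenuation_coefficient",
    "energy_absorption_ratio",
]

R_E = 2.8179403262e-13       # classical electron radius, cm
AVOGADRO = 6.02214076e23
ELECTRON_MASS_KEV = 511.0

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 1000.0

# Photoelectric parametrization, anchored so that water's photoelectric
# mass coefficient at 10 keV equals 4.94 cm^2/g.
_PE_EXPONENT = 3.2
_PE_K = 12.17  # tau/rho = _PE_K * sum(w Z^4.5 / A) * E_keV^-3.2


def klein_nishina_total(energy_kev):
    """Klein-Nishina total cross section per electron (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_MASS_KEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E**2 * (t1 + t2 + t3)


def klein_nishina_scatter(energy_kev):
    """KN cross section weighted by the scattered-photon energy fraction (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_MASS_KEV
    t1 = np.log1p(2 * a) / a**3
    t2 = 2 * (1 + a) * (2 * a**2 - 2 * a - 1) / (a**2 * (1 + 2 * a) ** 2)
    t3 = 8 * a**2 / (3 * (1 + 2 * a) ** 3)
    return np.pi * R_E**2 * (t1 + t2 + t3)


def klein_nishina_transfer(energy_kev):
    """KN energy-transfer cross section (energy given to electrons), cm^2."""
    return klein_nishina_total(energy_kev) - klein_nishina_scatter(energy_kev)


def _electrons_per_gram(composition: dict[str, float]) -> float:
    return AVOGADRO * sum(w * ELEMENTS[el][0] / ELEMENTS[el][1]
                          for el, w in composition.items())


def _pe_factor(composition: dict[str, float]) -> float:
    return sum(w * ELEMENTS[el][0] ** 4.5 / ELEMENTS[el][1]
               for el, w in composition.items())


def mass_coefficients(material: Material, energies_kev) -> dict[str, np.ndarray]:
    """Mass attenuation / energy-absorption coefficients (cm^2/g) on a grid."""
    e = np.asarray(energies_kev, dtype=float)
    ne = _electrons_per_gram(material.composition)
    compton = ne * klein_nishina_total(e)
    compton_tr = ne * klein_nishina_transfer(e)
    pe = _PE_K * _pe_factor(material.composition) * e ** (-_PE_EXPONENT)
    return {
        "compton": compton,
        "photoelectric": pe,
        "total": compton + pe,
        "muen": compton_tr + pe,
    }


@dataclass
class CrossSectionTable:
    """Tabulated mass coefficients for all materials on a common energy grid.

    Arrays are shaped (n_materials, n_energies), units cm^2/g.
    """

    energies_kev: np.ndarray
    total: np.ndarray
    compton: np.ndarray
    photoelectric: np.ndarray
    muen: np.ndarray
    material_table: MaterialTable = field(repr=False, default=None)

    def __post_init__(self):
        if self.material_table is None:
            self.material_table = default_material_table()
        if np.any(self.muen > self.total * (1 + 1e-9)):
            raise ValueError("mu_en/rho must not exceed mu/rho")

    # -- lookups -----------------------------------------------------------
    def _channel(self, channel: str) -> np.ndarray:
        try:
            return getattr(self, channel)
        except AttributeError:
            raise ValueError(f"unknown channel {channel!r}") from None

    def mass_coefficient(self, material_id: int, energy_kev, channel="total"):
        """Log-log interpolated mass coefficient (cm^2/g)."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies_kev[0]) or np.any(e > self.energies_kev[-1]):
            raise ValueError("energy outside table range "
                             f"[{self.energies_kev[0]}, {self.energies_kev[-1]}] keV")
        tab = self._channel(channel)[int(material_id)]
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev), np.log(tab)))
        return out if out.ndim else float(out)

    def linear_attenuation(self, material_id: int, energy_kev, channel="total"):
        """mu (1/cm) at the material's nominal density."""
        rho = self.material_table.material(material_id).density
        return self.mass_coefficient(material_id, energy_kev, channel) * rho

    def energy_absorption_ratio(self, target_id: int, source_id: int,
                                energy_kev=511.0):
        """(mu_en/rho)_target / (mu_en/rho)_source at the given energy."""
        return (self.mass_coefficient(target_id, energy_kev, "muen")
                / self.mass_coefficient(source_id, energy_kev, "muen"))

    # -- (de)serialization -------------------------------------------------
    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("material_id,energy_kev,mu_rho_total,mu_rho_compton,"
                  "mu_rho_photoelectric,muen_rho\n")
        for m in range(self.total.shape[0]):
            for j, e in enumerate(self.energies_kev):
                buf.write(f"{m},{e:.8e},{self.total[m, j]:.8e},"
                          f"{self.compton[m, j]:.8e},"
                          f"{self.photoelectric[m, j]:.8e},"
                          f"{self.muen[m, j]:.8e}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, material_table: MaterialTable | None = None):
        rows = np.loadtxt(io.StringIO(text), delimiter=",", skiprows=1)
        mats = rows[:, 0].astype(int)
        n_mat = mats.max() + 1
        energies = np.unique(rows[:, 1])
        n_e = energies.size
        order = np.lexsort((rows[:, 1], mats))
        rows = rows[order]
        shape = (n_mat, n_e)
        return cls(
            energies_kev=energies,
            total=rows[:, 2].reshape(shape),
            compton=rows[:, 3].reshape(shape),
            photoelectric=rows[:, 4].reshape(shape),
            muen=rows[:, 5].reshape(shape),
            material_table=material_table,
        )

    # -- dense grids for the transport engine ------------------------------
    def dense_grids(self, n: int = 256):
        """Mass coefficients resampled on a dense log grid for fast lookup.

        Returns (log_e0, dlog, mu_rho_total, mu_rho_pe, muen_rho) where the
        arrays are (n_materials, n) and index j corresponds to energy
        exp(log_e0 + j*dlog) keV.
        """
        loge = np.linspace(np.log(self.energies_kev[0]),
                           np.log(self.energies_kev[-1]), n)
        e = np.exp(loge)
        n_mat = self.total.shape[0]
        tot = np.empty((n_mat, n))
        pe = np.empty((n_mat, n))
        men = np.empty((n_mat, n))
        for m in range(n_mat):
            tot[m] = self.mass_coefficient(m, e, "total")
            pe[m] = self.mass_coefficient(m, e, "photoelectric")
            men[m] = self.mass_coefficient(m, e, "muen")
        return loge[0], loge[1] - loge[0], tot, pe, men


def build_cross_section_table(material_table: MaterialTable | None = None,
                              n_nodes: int = 40) -> CrossSectionTable:
    """Compute the table from material compositions (40 log nodes, 10-1000 keV)."""
    mt = material_table or default_material_table()
    e = np.geomspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, n_nodes)
    arrays = {k: [] for k in ("total", "compton", "photoelectric", "muen")}
    for m in mt.materials:
        coeffs = mass_coefficients(m, e)
        for k in arrays:
            arrays[k].append(coeffs[k])
    return CrossSectionTable(
        energies_kev=e,
        total=np.array(arrays["total"]),
        compton=np.array(arrays["compton"]),
        photoelectric=np.array(arrays["photoelectric"]),
        muen=np.array(arrays["muen"]),
        material_table=mt,
    )


_DEFAULT: CrossSectionTable | None = None


def default_cross_sections() -> CrossSectionTable:
    """The packaged CSV table (loaded once)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("voxdose.data").joinpath("cross_sections.csv")
        _DEFAULT = CrossSectionTable.from_csv(ref.read_text())
    return _DEFAULT


def attenuation_coefficient(material_id: int, energy_kev, channel="total"):
    """Linear attenuation coefficient mu (1/cm) at nominal material density."""
    return default_cross_sections().linear_attenuation(material_id, energy_kev,
                                                       channel)


def energy_absorption_ratio(target_id: int, source_id: int, energy_kev=511.0):
    """Mass energy-absorption coefficient ratio, target over source."""
    return default_cross_sections().energy_absorption_ratio(
        target_id, source_id, energy_kev)
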