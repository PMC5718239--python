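"""Energy-dependent photon attenuation and polychromatic tube spectra.

The attenuation model keeps only the two interactions that drive marker
contrast in the diagnostic and megavoltage range:

* incoherent (Compton) scattering, with the exact Klein--Nishina total
  cross-section per electron, so the Compton part of ``mu`` is proportional
  to the electron density of the material;
* photoelectric absorption, modeled as ``k_pe * n_e * Z_eff**3 / E**3``
  (the textbook Z^3/E^3 scaling), with a single scale constant ``k_pe``
  calibrated so that soft tissue's photoelectric and Compton contributions
  are equal at 26 keV.

Coherent scattering, pair production and characteristic lines are
deliberately omitted: the model is meant to reproduce contrast *trends*
for high-Z versus tissue-like inserts, not NIST tables.

Tube spectra use a Kramers bremsstrahlung shape, hardened by an
aluminum-equivalent filter, binned at 1 keV by default.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DomainError, MaterialLookupError

__all__ = [
    "AVOGADRO",
    "ELECTRON_REST_KEV",
    "CLASSICAL_ELECTRON_RADIUS_CM",
    "THOMSON_CROSS_SECTION",
    "K_PE_DEFAULT",
    "Material",
    "MaterialTable",
    "Spectrum",
    "default_materials",
    "load_material_table",
    "klein_nishina_cross_section",
    "attenuation_coefficient",
    "generate_spectrum",
    "effective_energy",
    "electron_density",
]

AVOGADRO = 6.02214076e23
ELECTRON_REST_KEV = 510.99895
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
#: Thomson total cross-section, cm^2 per electron (zero-energy Compton limit).
THOMSON_CROSS_SECTION = 8.0 * math.pi / 3.0 * CLASSICAL_ELECTRON_RADIUS_CM**2


def electron_density(mass_density: float, z_over_a: float) -> float:
    """Electrons per cm^3 from mass density [g/cm^3] and Z/A [mol e-/g]."""
    return mass_density * z_over_a * AVOGADRO


@dataclass(frozen=True)
class Material:
    """Physical description of a homogeneous material.

    Attributes
    ----------
    name:
        Registry label, e.g. ``"gold"``.
    z_eff:
        Effective atomic number (dimensionless, >= 1 for physical matter).
    mass_density:
        g/cm^3.
    electron_density:
        electrons/cm^3.
    """

    name: str
    z_eff: float
    mass_density: float
    electron_density: float

    def __post_init__(self) -> None:
        if self.z_eff < 1 and self.electron_density > 0:
            raise DomainError(f"material {self.name!r}: z_eff must be >= 1")
        if self.mass_density < 0 or self.electron_density < 0:
            raise DomainError(f"material {self.name!r}: densities must be >= 0")


def _mat(name: str, z_eff: float, rho: float, z_over_a: float) -> Material:
    return Material(name, z_eff, rho, electron_density(rho, z_over_a))


# Default stand-in constants: the markers' exact alloy/polymer chemistry is
# proprietary, so these are representative elemental/compound values and are
# overridable through the TOML configuration.
_DEFAULT_SPECS: dict[str, tuple[float, float, float]] = {
    # name: (z_eff, mass_density g/cm3, Z/A)
    "gold": (79.0, 19.3, 0.40108),
    "carbon": (6.0, 1.8, 0.49955),
    "polymer": (6.6, 1.2, 0.54000),
    "soft_tissue": (7.4, 1.0, 0.55000),
    "air": (7.6, 1.2e-3, 0.49919),
    "aluminum": (13.0, 2.699, 0.48181),
}

REQUIRED_MATERIALS = ("gold", "carbon", "polymer", "soft_tissue", "air")


class MaterialTable(dict):
    """Mapping of material name -> :class:`Material` with strict lookup."""

    def __missing__(self, key: str) -> Material:
        raise MaterialLookupError(f"unknown material {key!r}; registered: {sorted(self)}")

    def register(self, material: Material) -> None:
        self[material.name] = material


def default_materials() -> MaterialTable:
    """The built-in material table (gold, carbon, polymer, soft_tissue, air, aluminum)."""
    table = MaterialTable()
    for name, (z, rho, zoa) in _DEFAULT_SPECS.items():
        table.register(_mat(name, z, rho, zoa))
    return table


def load_material_table(path: str | Path) -> MaterialTable:
    """Material table from a TOML file; entries missing from the file keep defaults.

    Expected layout::

        [materials.gold]
        z_eff = 79.0
        mass_density = 19.3
        z_over_a = 0.40108        # or electron_density = ...
    """
    table = default_materials()
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for name, entry in cfg.get("materials", {}).items():
        base = table.get(name)
        z = float(entry.get("z_eff", base.z_eff if base else 7.4))
        rho = float(entry.get("mass_density", base.mass_density if base else 1.0))
        if "electron_density" in entry:
            ne = float(entry["electron_density"])
        elif "z_over_a" in entry:
            ne = electron_density(rho, float(entry["z_over_a"]))
        elif base is not None and rho == base.mass_density:
            ne = base.electron_density
        else:
            ne = electron_density(rho, 0.55)
        table.register(Material(name, z, rho, ne))
    return table


def klein_nishina_cross_section(energy_kev):
    """Total Klein--Nishina cross-section [cm^2/electron] at photon energy [keV].

    Closed form in the reduced energy ``alpha = E / m_e c^2``; strictly
    positive and strictly decreasing, with the Thomson limit as alpha -> 0.
    Accepts scalars or arrays.
    """
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise DomainError("photon energy must be positive")
    a = e / ELECTRON_REST_KEV
    # log1p keeps the small-alpha cancellation benign down to ~1 eV.
    l = np.log1p(2.0 * a)
    term1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - l / a)
    term2 = l / (2.0 * a)
    term3 = -(1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    sigma = 2.0 * math.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * (term1 + term2 + term3)
    if sigma.ndim == 0:
        return float(sigma)
    return sigma


def _calibrate_k_pe(material: Material, energy_kev: float) -> float:
    """k_pe such that the material's photoelectric and Compton terms match at ``energy_kev``."""
    sigma = klein_nishina_cross_section(energy_kev)
    return sigma * energy_kev**3 / material.z_eff**3


#: Photoelectric scale constant [cm^2 keV^3 / electron]: soft tissue's
#: photoelectric and Compton contributions are equal at 26 keV.
K_PE_DEFAULT = _calibrate_k_pe(_mat(*(("soft_tissue",) + _DEFAULT_SPECS["soft_tissue"])), 26.0)


def attenuation_coefficient(material: Material, energy_kev, k_pe: float = K_PE_DEFAULT):
    """Linear attenuation coefficient mu(E) [1/cm].

    ``mu = n_e * sigma_KN(E) + k_pe * n_e * Z_eff^3 / E^3``.
    Vectorized over energy.
    """
    if k_pe < 0:
        raise DomainError("k_pe must be >= 0")
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise DomainError("photon energy must be positive")
    sigma = np.asarray(klein_nishina_cross_section(e))
    mu = material.electron_density * (sigma + k_pe * material.z_eff**3 / e**3)
    if mu.ndim == 0:
        return float(mu)
    return mu


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon spectrum: strictly increasing bin-center energies [keV]
    and non-negative relative fluence weights normalized to unit sum."""

    energies: np.ndarray
    weights: np.ndarray
    kvp: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.size == 0:
            raise DomainError("spectrum must contain at least one bin")
        if e.shape != w.shape:
            raise DomainError("energies and weights must have the same shape")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise DomainError("energies must be positive and strictly increasing")
        if np.any(w < 0) or not np.any(w > 0):
            raise DomainError("weights must be non-negative with positive total")
        if self.kvp is not None and e.max() > self.kvp + 1e-9:
            raise DomainError("spectrum extends above its generating kVp")
        w = w / w.sum()
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "Spectrum":
        return cls(np.array([float(energy_kev)]), np.array([1.0]))

    @property
    def n_bins(self) -> int:
        return int(self.energies.size)

    def filtered(self, material: Material, thickness_cm: float, k_pe: float = K_PE_DEFAULT) -> "Spectrum":
        """Spectrum after Beer--Lambert filtration through ``thickness_cm`` of ``material``."""
        if thickness_cm < 0:
            raise DomainError("filtration thickness must be >= 0")
        mu = attenuation_coefficient(material, self.energies, k_pe)
        return replace(self, weights=self.weights * np.exp(-np.asarray(mu) * thickness_cm))


def generate_spectrum(
    kvp: float,
    filtration_mm_al: float = 2.5,
    bin_width: float = 1.0,
    low_energy_cutoff: float = 10.0,
    k_pe: float = K_PE_DEFAULT,
    materials: MaterialTable | None = None,
) -> Spectrum:
    """Kramers bremsstrahlung spectrum at ``kvp`` with aluminum-equivalent filtration.

    Unfiltered bin weight at energy E is proportional to ``(kvp - E) / E``;
    filtration multiplies by ``exp(-mu_Al(E) * t)``; the result is renormalized.
    """
    if kvp <= bin_width:
        raise DomainError("kvp must exceed the bin width")
    if filtration_mm_al < 0:
        raise DomainError("filtration must be >= 0")
    start = max(low_energy_cutoff, bin_width) + bin_width / 2.0
    energies = np.arange(start, kvp, bin_width)
    if energies.size == 0:
        raise DomainError("no spectral bins between the cutoff and kvp")
    weights = (kvp - energies) / energies
    spectrum = Spectrum(energies, weights, kvp=kvp)
    if filtration_mm_al > 0:
        al = (materials or default_materials())["aluminum"]
        spectrum = spectrum.filtered(al, filtration_mm_al / 10.0, k_pe)
    return spectrum


def effective_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy [keV] of a spectrum."""
    return float(np.sum(spectrum.energies * spectrum.weights))
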