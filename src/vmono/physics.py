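"""X-ray physics: attenuation tables, materials, source spectra, detector response.

The energy range of interest for 60 kVp small-animal imaging is 5-60 keV.
Elemental mass-attenuation coefficients are shipped as plain-text tables
(``data/attenuation/<symbol>.txt``) following the standard NIST/XCOM
reference values (total attenuation including coherent scatter) and are
interpolated log-log.  Absorption edges are stored as duplicated energy rows;
a query exactly at an edge energy takes the above-edge branch.

The polyenergetic source is a filtered Kramers bremsstrahlung model: the
unfiltered photon fluence per energy bin is proportional to ``kvp/E - 1``,
hardened by Beer-Lambert transmission through the inherent beryllium and the
aluminum spectral filtration.  Tungsten characteristic K-lines are not
excited below 69 kVp, so filtered bremsstrahlung is an adequate model of a
60 kVp tube; anode-angle and heel effects are not modelled.  An externally
computed spectrum can be loaded from a two-column text file instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EnergyGrid",
    "Spectrum",
    "Material",
    "AttenuationDB",
    "DetectorModel",
    "default_grid",
    "elemental_mu_rho",
    "material_mu",
    "kramers_spectrum",
    "filter_spectrum",
    "mono_spectrum",
    "detector_response",
    "load_spectrum",
    "save_spectrum",
    "MATERIALS",
    "tissue",
    "BERYLLIUM",
    "ALUMINUM",
    "GRAPHITE",
    "CSI",
]

MONO_ENERGY_KEV = 35.0  #: default virtual monoenergetic imaging energy


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies in keV (1 keV bin centers by default)."""

    energies: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("energy grid must be a non-empty 1-D array")
        if np.any(e <= 0):
            raise ValueError("all energies must be > 0 keV")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        object.__setattr__(self, "energies", e)

    def __len__(self):
        return self.energies.size


def default_grid(lo: float = 5.0, hi: float = 60.0, step: float = 1.0) -> EnergyGrid:
    """The default 5-60 keV grid in 1 keV bins (bin-center convention)."""
    n = int(round((hi - lo) / step)) + 1
    return EnergyGrid(lo + step * np.arange(n))


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin of an :class:`EnergyGrid`."""

    grid: EnergyGrid
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.energies.shape:
            raise ValueError("weights must match the energy grid")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("spectrum must have at least one positive weight")
        object.__setattr__(self, "weights", w)

    @property
    def energies(self) -> np.ndarray:
        return self.grid.energies

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy in keV."""
        return float(np.sum(self.energies * self.weights) / np.sum(self.weights))

    def normalized(self) -> "Spectrum":
        return Spectrum(self.grid, self.weights / np.sum(self.weights))

    @property
    def is_monoenergetic(self) -> bool:
        return int(np.count_nonzero(self.weights)) == 1


@dataclass(frozen=True)
class Material:
    """A named mixture of elements with a mass density in g/cm^3.

    ``composition`` maps element symbols to mass fractions, which must sum
    to one within 1e-9.
    """

    name: str
    composition: dict
    density: float

    def __post_init__(self):
        if not self.composition:
            raise ValueError(f"material {self.name!r} has an empty composition")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total!r}, expected 1"
            )
        if any(f < 0 for f in self.composition.values()):
            raise ValueError(f"negative mass fraction in {self.name!r}")
        if self.density <= 0:
            raise ValueError(f"density of {self.name!r} must be > 0")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, dict(self.composition), density)


def _normalize(comp: dict) -> dict:
    total = sum(comp.values())
    return {k: v / total for k, v in comp.items()}


class AttenuationDB:
    """Per-element mass-attenuation tables with log-log interpolation.

    Tables are read once from the package data directory.  Duplicated
    abscissae encode absorption edges; queries exactly at the edge energy
    return the above-edge branch.
    """

    def __init__(self, data_dir: str | Path | None = None):
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if data_dir is None:
            root = resources.files("vmono").joinpath("data/attenuation")
        else:
            root = Path(data_dir)
        for entry in sorted(root.iterdir()):
            name = getattr(entry, "name", str(entry))
            if not name.endswith(".txt"):
                continue
            rows = np.loadtxt(str(entry), comments="#", ndmin=2)
            self._tables[name[:-4]] = (rows[:, 0].copy(), rows[:, 1].copy())

    @property
    def elements(self) -> list[str]:
        return sorted(self._tables)

    def energy_range(self, element: str) -> tuple[float, float]:
        e, _ = self._table(element)
        return float(e[0]), float(e[-1])

    def _table(self, element: str):
        try:
            return self._tables[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} not in attenuation database "
                f"(available: {', '.join(self.elements)})"
            ) from None

    def mu_rho(self, element: str, energies) -> np.ndarray:
        """Mass attenuation mu/rho [cm^2/g] at the given energies [keV]."""
        e_tab, mu_tab = self._table(element)
        e = np.atleast_1d(np.asarray(
            energies.energies if isinstance(energies, EnergyGrid) else energies,
            dtype=float,
        ))
        if np.any(e < e_tab[0]) or np.any(e > e_tab[-1]):
            raise ValueError(
                f"energy out of table range for {element}: "
                f"[{e_tab[0]:g}, {e_tab[-1]:g}] keV"
            )
        # searchsorted side='right' puts an exact edge query on the
        # above-edge branch and an exact knot on its own left endpoint.
        idx = np.searchsorted(e_tab, e, side="right")
        idx = np.clip(idx, 1, len(e_tab) - 1)
        lo, hi = idx - 1, idx
        x0, x1 = np.log(e_tab[lo]), np.log(e_tab[hi])
        y0, y1 = np.log(mu_tab[lo]), np.log(mu_tab[hi])
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(x1 > x0, (np.log(e) - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
        return np.exp(y0 + frac * (y1 - y0))


_DEFAULT_DB: AttenuationDB | None = None


def get_db() -> AttenuationDB:
    """The shared database instance backed by the packaged tables."""
    global _DEFAULT_DB
    if _DEFAULT_DB is None:
        _DEFAULT_DB = AttenuationDB()
    return _DEFAULT_DB


def elemental_mu_rho(element: str, energies, db: AttenuationDB | None = None) -> np.ndarray:
    """Tabulated elemental mu/rho [cm^2/g], log-log interpolated."""
    return (db or get_db()).mu_rho(element, energies)


def material_mu(material: Material, energies, db: AttenuationDB | None = None) -> np.ndarray:
    """Linear attenuation mu(E) [1/cm] of a material via the mixture rule.

    mu(E) = rho * sum_i w_i * (mu/rho)_i(E)
    """
    db = db or get_db()
    e = energies
    acc = None
    for sym, w in material.composition.items():
        term = w * db.mu_rho(sym, e)
        acc = term if acc is None else acc + term
    return material.density * acc


def kramers_spectrum(kvp: float, grid: EnergyGrid | None = None) -> Spectrum:
    """Unfiltered Kramers bremsstrahlung: fluence per bin ~ max(0, kvp/E - 1)."""
    grid = grid or default_grid()
    if kvp <= grid.energies[0]:
        raise ValueError(f"kvp={kvp} must exceed the lowest grid energy")
    w = np.maximum(0.0, kvp / grid.energies - 1.0)
    return Spectrum(grid, w)


def filter_spectrum(spectrum: Spectrum, layers, db: AttenuationDB | None = None) -> Spectrum:
    """Harden a spectrum through absorbing layers [(Material, thickness cm), ...]."""
    db = db or get_db()
    w = spectrum.weights.copy()
    for material, t_cm in layers:
        if t_cm < 0:
            raise ValueError(f"negative layer thickness: {t_cm}")
        if t_cm == 0:
            continue
        mu = material_mu(material, spectrum.grid, db)
        w = w * np.exp(-mu * t_cm)
    return Spectrum(spectrum.grid, w)


def mono_spectrum(energy: float = MONO_ENERGY_KEV, db: AttenuationDB | None = None) -> Spectrum:
    """A single-bin spectrum of unit weight exactly at ``energy`` keV."""
    db = db or get_db()
    lo, hi = db.energy_range("O")
    if not (lo <= energy <= hi):
        raise ValueError(f"mono energy {energy} keV outside table range [{lo}, {hi}]")
    return Spectrum(EnergyGrid(np.array([float(energy)])), np.array([1.0]))


@dataclass(frozen=True)
class DetectorModel:
    """Energy response of the flat-panel detector.

    modes:
      - ``ideal-photon-counting``: D(E) = 1
      - ``energy-integrating``: D(E) = E
      - ``energy-integrating-with-CsI``: D(E) = E * T_plate(E) * A_CsI(E),
        an energy-integrating panel behind a protective carbon entrance plate,
        weighted by the absorbed fraction in the CsI scintillator.
    """

    mode: str = "energy-integrating-with-CsI"
    scintillator_um: float = 600.0
    plate_material: Material | None = None
    plate_thickness_cm: float = 0.1

    MODES = ("ideal-photon-counting", "energy-integrating", "energy-integrating-with-CsI")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValueError(f"unknown detector mode {self.mode!r}; choose from {self.MODES}")


def detector_response(grid: EnergyGrid, model: DetectorModel,
                      db: AttenuationDB | None = None) -> np.ndarray:
    """Detector response weights D(E) >= 0 on the grid."""
    db = db or get_db()
    e = grid.energies
    if model.mode == "ideal-photon-counting":
        return np.ones_like(e)
    if model.mode == "energy-integrating":
        return e.copy()
    plate = model.plate_material or GRAPHITE
    t_scint_cm = model.scintillator_um * 1e-4
    transmission = np.exp(-material_mu(plate, grid, db) * model.plate_thickness_cm)
    absorbed = 1.0 - np.exp(-material_mu(CSI, grid, db) * t_scint_cm)
    return e * transmission * absorbed


def imaging_spectrum(kvp: float = 60.0, grid: EnergyGrid | None = None,
                   db: AttenuationDB | None = None) -> Spectrum:
    """The default 60 kVp imaging spectrum: Kramers + 0.8 mm Be + 1.0 mm Al."""
    db = db or get_db()
    raw = kramers_spectrum(kvp, grid)
    return filter_spectrum(raw, [(BERYLLIUM, 0.08), (ALUMINUM, 0.1)], db)


def save_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text (energy keV, relative fluence)."""
    data = np.column_stack([spectrum.energies, spectrum.weights])
    np.savetxt(path, data, header="energy_keV  relative_fluence", fmt="%.8g")


def load_spectrum(path) -> Spectrum:
    data = np.loadtxt(path, ndmin=2)
    return Spectrum(EnergyGrid(data[:, 0]), data[:, 1])


# --------------------------------------------------------------------------
# Reference material library
# --------------------------------------------------------------------------

BERYLLIUM = Material("beryllium", {"Be": 1.0}, 1.848)
ALUMINUM = Material("aluminum", {"Al": 1.0}, 2.699)
GRAPHITE = Material("graphite", {"C": 1.0}, 1.70)
CSI = Material("cesium iodide", {"Cs": 0.51155, "I": 0.48845}, 4.51)

#: Reference tissue library (ICRU-44-style compositions, mass fractions).
#: Fifteen entries spanning the tissue diversity of a small rodent plus the
#: water and air needed for inserts and background.
MATERIALS: dict[str, Material] = {
    "air": Material("air", _normalize({"N": 0.755, "O": 0.232, "C": 0.013}), 1.205e-3),
    "water": Material("water", {"H": 0.111894, "O": 0.888106}, 1.0),
    "soft_tissue": Material("soft_tissue", _normalize({
        "H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602, "Na": 0.001,
        "P": 0.002, "S": 0.003, "Cl": 0.002, "K": 0.002}), 1.03),
    "muscle": Material("muscle", _normalize({
        "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710, "Na": 0.001,
        "P": 0.002, "S": 0.003, "Cl": 0.001, "K": 0.004}), 1.05),
    "adipose": Material("adipose", _normalize({
        "H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "Na": 0.001,
        "S": 0.001, "Cl": 0.001}), 0.95),
    "skin": Material("skin", _normalize({
        "H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "Na": 0.002,
        "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.001}), 1.09),
    "cortical_bone": Material("cortical_bone", _normalize({
        "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
        "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}), 1.92),
    "spongiosa": Material("spongiosa", _normalize({
        "H": 0.085, "C": 0.404, "N": 0.058, "O": 0.367, "Na": 0.001,
        "Mg": 0.001, "P": 0.034, "S": 0.002, "Cl": 0.002, "K": 0.001,
        "Ca": 0.044, "Fe": 0.001}), 1.18),
    "cartilage": Material("cartilage", _normalize({
        "H": 0.096, "C": 0.099, "N": 0.022, "O": 0.744, "Na": 0.005,
        "P": 0.022, "S": 0.009, "Cl": 0.003}), 1.10),
    "brain": Material("brain", _normalize({
        "H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "Na": 0.002,
        "P": 0.004, "S": 0.002, "Cl": 0.003, "K": 0.003}), 1.04),
    "lung": Material("lung", _normalize({
        "H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "Na": 0.002,
        "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002}), 0.26),
    "liver": Material("liver", _normalize({
        "H": 0.102, "C": 0.139, "N": 0.030, "O": 0.716, "Na": 0.002,
        "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}), 1.06),
    "kidney": Material("kidney", _normalize({
        "H": 0.103, "C": 0.132, "N": 0.030, "O": 0.724, "Na": 0.002,
        "P": 0.002, "S": 0.002, "Cl": 0.002, "K": 0.002, "Ca": 0.001}), 1.05),
    "heart": Material("heart", _normalize({
        "H": 0.104, "C": 0.139, "N": 0.029, "O": 0.718, "Na": 0.001,
        "P": 0.002, "S": 0.002, "Cl": 0.002, "K": 0.003}), 1.05),
    "blood": Material("blood", _normalize({
        "H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "Na": 0.001,
        "P": 0.001, "S": 0.002, "Cl": 0.003, "K": 0.002, "Fe": 0.001}), 1.06),
}


def tissue(name: str) -> Material:
    """Look up a material from the reference tissue library."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown tissue {name!r}; available: {', '.join(sorted(MATERIALS))}"
        ) from None
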