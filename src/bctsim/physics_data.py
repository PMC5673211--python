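"""Polychromatic tungsten-anode spectra and material attenuation data.

The normative data live in plain-text tables under :mod:`bctsim.data`:
per-1-keV-bin polynomial coefficients in tube potential for the tungsten
bremsstrahlung continuum (TASMIP-style layout) plus a small K-line table,
and mass attenuation coefficients on a 1-keV grid from 10 to 100 keV for
the phantom and fixture materials.  ``scripts/make_physics_tables.py`` in
the repository documents and regenerates both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "MaterialTable",
    "available_materials",
    "get_material",
    "make_spectrum",
    "mean_energy",
    "mu_lookup",
    "mass_attenuation",
]

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 100.0


def _data_path(name: str) -> Path:
    return Path(resources.files("bctsim").joinpath("data", name))


def _read_csv(path: Path) -> dict[str, np.ndarray]:
    """Parse a '#'-commented CSV with one header row into named columns."""
    rows = [ln for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    names = rows[0].split(",")
    data = np.array([[float(v) for v in ln.split(",")] for ln in rows[1:]])
    return {n: data[:, i] for i, n in enumerate(names)}


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence per 1-keV energy bin (relative units)."""

    energies_kev: np.ndarray
    fluence: np.ndarray
    kvp: float
    filtration: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if np.any(self.fluence < 0):
            raise ValueError("negative fluence")
        if not np.any(self.fluence > 0):
            raise ValueError("spectrum has no positive bins")
        if np.any(self.fluence[self.energies_kev > self.kvp] > 0):
            raise ValueError("fluence above the tube potential")

    def to_text(self, path: str | Path) -> None:
        """Write as two-column text (keV, relative fluence)."""
        np.savetxt(path, np.column_stack([self.energies_kev, self.fluence]),
                   fmt="%.6g", header="energy_kev fluence")

    @classmethod
    def from_text(cls, path: str | Path, kvp: float | None = None) -> "Spectrum":
        arr = np.loadtxt(path)
        e, phi = arr[:, 0], arr[:, 1]
        if kvp is None:
            kvp = float(e[phi > 0].max())
        return cls(e, phi, kvp)


@dataclass(frozen=True)
class MaterialTable:
    """Energy-dependent attenuation for one material.

    ``mass_atten`` is mu/rho in cm^2/g on the bundled 1-keV grid;
    linear attenuation is returned in 1/mm (density * mu/rho / 10).
    """

    name: str
    density_g_cm3: float
    energies_kev: np.ndarray = field(repr=False)
    mass_atten_cm2_g: np.ndarray = field(repr=False)

    def mu_mm(self, energy_kev) -> np.ndarray:
        """Linear attenuation coefficient (1/mm), log-log interpolated."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        mu_rho = np.exp(np.interp(np.log(e), np.log(self.energies_kev),
                                  np.log(self.mass_atten_cm2_g)))
        return self.density_g_cm3 * mu_rho / 10.0


@lru_cache(maxsize=1)
def _load_tables() -> dict[str, MaterialTable]:
    raw = _read_csv(_data_path("mass_attenuation.csv"))
    dens = json.loads(_data_path("materials.json").read_text())["densities_g_cm3"]
    energies = raw.pop("energy_kev")
    return {name: MaterialTable(name, float(dens[name]), energies, col)
            for name, col in raw.items()}


def available_materials() -> list[str]:
    return sorted(_load_tables())


def get_material(name: str) -> MaterialTable:
    try:
        return _load_tables()[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; have {available_materials()}") from None


def mu_lookup(material: str, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient (1/mm) for a named material."""
    return get_material(material).mu_mm(energy_kev)


def mass_attenuation(material: str, energy_kev) -> np.ndarray:
    """Mass attenuation coefficient (cm^2/g), log-log interpolated."""
    m = get_material(material)
    e = np.asarray(energy_kev, dtype=float)
    return np.exp(np.interp(np.log(e), np.log(m.energies_kev),
                            np.log(m.mass_atten_cm2_g)))


@lru_cache(maxsize=1)
def _spectrum_model():
    poly = _read_csv(_data_path("tungsten_spectrum_poly.csv"))
    lines = _read_csv(_data_path("tungsten_klines.csv"))
    meta = {}
    for ln in _data_path("tungsten_klines.csv").read_text().splitlines():
        if ln.startswith("#") and "edge_kev=" in ln:
            for tok in ln.lstrip("# ").split():
                k, v = tok.split("=")
                meta[k] = float(v)
    return poly, lines, meta


def make_spectrum(kvp: float,
                  filtration: list[tuple[str, float]] | None = None) -> Spectrum:
    """Tungsten-anode spectrum at ``kvp``, optionally Beer-filtered.

    Parameters
    ----------
    kvp:
        Tube potential in kV, 20-100.
    filtration:
        Sequence of ``(material, thickness_mm)`` layers applied as
        ``exp(-mu * t)`` on top of the tabulated inherent filtration.
    """
    if not 20.0 <= kvp <= 100.0:
        raise ValueError("kvp outside the tabulated 20-100 range")
    poly, lines, meta = _spectrum_model()
    e = poly["energy_kev"]
    phi = np.clip(poly["c0"] + poly["c1"] * kvp, 0.0, None)
    phi[e >= kvp] = 0.0
    edge, coef, expn = meta["edge_kev"], meta["k_coef"], meta["k_exp"]
    if kvp > edge:
        total = coef * (kvp / edge - 1.0) ** expn * phi.sum()
        for line_e, strength in zip(lines["line_kev"], lines["strength"]):
            phi[np.searchsorted(e, line_e)] += strength * total
    filt = tuple((m, float(t)) for m, t in (filtration or []))
    for mat, t_mm in filt:
        phi = phi * np.exp(-mu_lookup(mat, e) * t_mm)
    return Spectrum(e, phi, float(kvp), filt)


def uniform_spectrum(kvp: float) -> Spectrum:
    """Flat photon-fluence spectrum: one unit per 1-keV bin up to ``kvp``.

    Feeding this to the polychromatic projector reproduces an unweighted
    per-bin energy sum — the equal-fluence convention some beam-hardening
    demonstrations use in place of a full anode model.  Its mean energy
    for a 60 kV cutoff is exactly 35 keV, the canonical monochromatic-
    assumption energy.
    """
    if not ENERGY_MIN_KEV < kvp <= ENERGY_MAX_KEV:
        raise ValueError("kvp outside the tabulated range")
    e = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + 0.5)
    return Spectrum(e, (e <= kvp).astype(float), float(kvp))


def mean_energy(s: Spectrum) -> float:
    """Photon-fluence-weighted mean energy in keV."""
    total = s.fluence.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    return float((s.fluence * s.energies_kev).sum() / total)
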