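"""Regenerate the plain-text physics tables bundled with ``bctsim``.

The package ships two kinds of normative data under ``src/bctsim/data``:

* ``mass_attenuation.csv`` + ``materials.json`` — mass attenuation
  coefficients (cm^2/g) on a 1-keV grid from 10 to 100 keV for the phantom
  and fixture materials, obtained by the elemental mixture rule from
  standard photon cross-section compilations (NIST/XCOM-style elemental
  values at the canonical grid energies, log-log PCHIP interpolated).
  Tissue compositions follow ICRU-44 / Hammerstein-style recipes reduced
  to their dominant elements (H, C, N, O, F) and renormalized; trace
  elements below 1 % by mass are omitted.

* ``tungsten_spectrum_poly.csv`` + ``tungsten_klines.csv`` — a
  TASMIP-style table of per-energy-bin polynomial coefficients in tube
  potential for a tungsten-anode spectrum.  The bremsstrahlung continuum
  follows a Kramers model hardened by a fixed aluminium-equivalent
  inherent filtration; characteristic tungsten K lines are added above
  the K edge.  The inherent filtration is the single calibration constant
  of the model: it is solved for so that the unfiltered 60 kVp spectrum
  has a photon-fluence-weighted mean energy of exactly 35 keV, the value
  conventionally quoted for measured tungsten spectra at that potential.

Run from the repository root:  python scripts/make_physics_tables.py
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

OUT = Path(__file__).resolve().parents[1] / "src" / "bctsim" / "data"

# ---------------------------------------------------------------------------
# Elemental mass attenuation coefficients (cm^2/g) at the canonical grid
# energies (keV).  Standard photon cross-section compilation values for the
# light elements that dominate soft tissue, PMMA, PTFE, water and aluminium.
# ---------------------------------------------------------------------------
GRID_KEV = np.array([10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0])

ELEMENTS = {
    "H":  [0.3854, 0.3764, 0.3695, 0.3570, 0.3458, 0.3355, 0.3260, 0.3091, 0.2944],
    "C":  [2.3730, 0.8071, 0.4420, 0.2562, 0.2076, 0.1871, 0.1753, 0.1610, 0.1514],
    "N":  [3.8790, 1.2360, 0.6178, 0.3066, 0.2288, 0.1980, 0.1817, 0.1639, 0.1529],
    "O":  [5.9520, 1.8360, 0.8651, 0.3779, 0.2585, 0.2132, 0.1907, 0.1678, 0.1551],
    "F":  [8.2050, 2.4920, 1.1330, 0.4487, 0.2828, 0.2214, 0.1920, 0.1639, 0.1496],
    "Al": [26.230, 7.9550, 3.4410, 1.1280, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704],
}

# (composition by mass fraction over dominant elements, density g/cm^3)
MATERIALS = {
    "water":      ({"H": 0.1119, "O": 0.8881}, 1.000),
    "adipose":    ({"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278}, 0.950),
    "glandular":  ({"H": 0.102, "C": 0.184, "N": 0.032, "O": 0.677}, 1.040),
    "skin":       ({"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645}, 1.090),
    "connective": ({"H": 0.094, "C": 0.207, "N": 0.062, "O": 0.622}, 1.120),
    "pmma":       ({"H": 0.0805, "C": 0.5998, "O": 0.3196}, 1.190),
    "ptfe":       ({"C": 0.2402, "F": 0.7598}, 2.200),
    "aluminum":   ({"Al": 1.0}, 2.699),
}

FINE_KEV = np.arange(10.0, 100.0 + 0.5, 1.0)


def element_fine(symbol: str) -> np.ndarray:
    """Log-log PCHIP interpolation of an elemental table onto the 1-keV grid."""
    y = np.asarray(ELEMENTS[symbol])
    interp = PchipInterpolator(np.log(GRID_KEV), np.log(y))
    return np.exp(interp(np.log(FINE_KEV)))


def build_attenuation() -> None:
    fine = {sym: element_fine(sym) for sym in ELEMENTS}
    cols, dens = {}, {}
    for name, (comp, rho) in MATERIALS.items():
        w = np.array(list(comp.values()))
        w = w / w.sum()  # renormalize over the retained elements
        mu_rho = sum(wi * fine[sym] for wi, sym in zip(w, comp))
        cols[name] = mu_rho
        dens[name] = rho

    header = (
        "# Mass attenuation coefficients (cm^2/g), 1-keV grid.\n"
        "# Computed by the elemental mixture rule from standard photon\n"
        "# cross-section compilation values (NIST/XCOM-style grids),\n"
        "# log-log PCHIP interpolated; dominant-element compositions.\n"
        "# Regenerate with scripts/make_physics_tables.py\n"
    )
    names = list(cols)
    lines = [header + "energy_kev," + ",".join(names)]
    for i, e in enumerate(FINE_KEV):
        lines.append(f"{e:.0f}," + ",".join(f"{cols[n][i]:.6g}" for n in names))
    (OUT / "mass_attenuation.csv").write_text("\n".join(lines) + "\n")
    (OUT / "materials.json").write_text(
        json.dumps({"densities_g_cm3": dens}, indent=1) + "\n"
    )
    return fine


# ---------------------------------------------------------------------------
# Tungsten spectrum model
# ---------------------------------------------------------------------------
K_EDGE = 69.525  # keV
# (line energy keV, relative line strength)
K_LINES = [(59.0, 0.50), (58.0, 0.29), (67.0, 0.15), (69.0, 0.06)]
K_COEF = 0.31    # total K-line fluence fraction scale
K_EXP = 1.65     # threshold-law exponent


def brems_fluence(kvp: float, t_al_mm: float, mu_al_mm: np.ndarray) -> np.ndarray:
    """Kramers continuum hardened by aluminium-equivalent inherent filtration."""
    phi = np.where(FINE_KEV < kvp, np.clip(kvp - FINE_KEV, 0, None) / FINE_KEV, 0.0)
    return phi * np.exp(-mu_al_mm * t_al_mm)


def mean_energy_60(t_al_mm: float, mu_al_mm: np.ndarray) -> float:
    phi = brems_fluence(60.0, t_al_mm, mu_al_mm)
    return float((phi * FINE_KEV).sum() / phi.sum())


def build_spectrum(al_fine: np.ndarray) -> None:
    mu_al_mm = al_fine * MATERIALS["aluminum"][1] / 10.0  # 1/mm
    # Calibrate inherent filtration: fluence-weighted mean of the 60 kVp
    # spectrum anchored at 35 keV.
    t_inh = brentq(lambda t: mean_energy_60(t, mu_al_mm) - 35.0, 0.1, 20.0)

    # Per-bin fluence is A(E)*(kvp - E) for E < kvp: a degree-1 polynomial
    # in tube potential with per-bin coefficients (TASMIP-style layout).
    amp = np.exp(-mu_al_mm * t_inh) / FINE_KEV
    c1 = amp
    c0 = -amp * FINE_KEV

    header = (
        "# Tungsten-anode bremsstrahlung fluence as per-1-keV-bin polynomials\n"
        "# in tube potential V (kVp): phi(E;V) = max(0, c0 + c1*V) for E < V.\n"
        "# Kramers continuum with {:.3f} mm Al-equivalent inherent filtration,\n"
        "# calibrated so the unfiltered 60 kVp spectrum has a 35 keV\n"
        "# fluence-weighted mean energy (TASMIP-style normative table).\n"
        "# Regenerate with scripts/make_physics_tables.py\n"
    ).format(t_inh)
    lines = [header + "energy_kev,c0,c1"]
    for e, a0, a1 in zip(FINE_KEV, c0, c1):
        lines.append(f"{e:.0f},{a0:.8e},{a1:.8e}")
    (OUT / "tungsten_spectrum_poly.csv").write_text("\n".join(lines) + "\n")

    lines = [
        "# Tungsten K fluorescence lines: fluence added to the 1-keV bin at\n"
        "# line_kev when V > edge_kev, as strength*K_COEF*(V/edge-1)^K_EXP\n"
        "# times the total continuum fluence.\n"
        f"# edge_kev={K_EDGE} k_coef={K_COEF} k_exp={K_EXP}\n"
        "line_kev,strength"
    ]
    for e, s in K_LINES:
        lines.append(f"{e:.0f},{s}")
    (OUT / "tungsten_klines.csv").write_text("\n".join(lines) + "\n")
    print(f"inherent filtration: {t_inh:.4f} mm Al")
    print(f"60 kVp mean energy:  {mean_energy_60(t_inh, mu_al_mm):.3f} keV")


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    fine = build_attenuation()
    build_spectrum(fine["Al"])
    print(f"tables written to {OUT}")
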