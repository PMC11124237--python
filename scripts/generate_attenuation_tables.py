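"""Generate the bundled per-element mass-attenuation tables.

Photoelectric cross sections are computed from Cromer-Liberman anomalous
scattering factors (f'') as provided by gemmi; incoherent scattering uses the
analytic Klein-Nishina total cross section for free electrons; coherent
scattering integrates the Thomson differential cross section weighted by the
squared IT92 independent-atom form factor (also from gemmi), with an s^-3
extrapolation of the form factor beyond the fit's validity range.

Run from the repository root:

    python scripts/generate_attenuation_tables.py

The output files under src/pcdsim/data/attenuation/ are committed; this
script only needs to be re-run if the element list or grid changes.
"""

from __future__ import annotations

import math
from pathlib import Path

import gemmi
import numpy as np

N_A = 6.02214076e23          # 1/mol
R_E = 2.8179403262e-13       # classical electron radius, cm
HC = 12.398419843320026      # keV * Angstrom
SIGMA_T = 6.6524587e-25      # Thomson cross section, cm^2

ELEMENTS = [
    "H", "Be", "C", "N", "O", "F", "Al", "Ar",
    "Cu", "Zn", "Br", "Cd", "I", "Te", "La", "Ce", "W",
]

# K-edge energies (keV), used to split the grid so that log-log
# interpolation never bridges an absorption edge.
K_EDGES = {
    "Cu": 8.979, "Zn": 9.659, "Br": 13.474, "Cd": 26.711,
    "I": 33.169, "Te": 31.814, "La": 38.925, "Ce": 40.443, "W": 69.525,
}

E_MIN, E_MAX, N_GRID = 1.0, 300.0, 90
FIT_SMAX = 2.0  # 1/Angstrom; IT92 validity boundary used for extrapolation


def photoelectric(z: int, weight: float, energies: np.ndarray) -> np.ndarray:
    out = np.empty_like(energies)
    for i, e in enumerate(energies):
        fpp = gemmi.cromer_liberman(z, float(e) * 1000.0)[1]
        lam_cm = HC / e * 1e-8
        out[i] = 2.0 * R_E * lam_cm * fpp * N_A / weight
    return out


def klein_nishina_total(energies: np.ndarray) -> np.ndarray:
    k = energies / 511.0
    return 0.75 * SIGMA_T * (
        (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
        + np.log(1 + 2 * k) / (2 * k)
        - (1 + 3 * k) / (1 + 2 * k) ** 2
    )


def incoherent(z: int, weight: float, energies: np.ndarray) -> np.ndarray:
    return klein_nishina_total(energies) * z * N_A / weight


def coherent(el: gemmi.Element, energies: np.ndarray, n: int = 3000) -> np.ndarray:
    it = el.it92
    f_boundary = it.calculate_sf(FIT_SMAX**2)
    out = np.empty_like(energies)
    for i, e in enumerate(energies):
        lam = HC / e  # Angstrom
        s = np.linspace(0.0, 1.0 / lam, n)  # sin(theta/2)/lambda
        f = np.array([it.calculate_sf(x) for x in s**2])
        tail = s > FIT_SMAX
        if tail.any():
            f[tail] = f_boundary * (FIT_SMAX / s[tail]) ** 3
        cos_t = 1.0 - 2.0 * (lam * s) ** 2
        sigma = np.trapezoid((1 + cos_t**2) * f**2 * 4 * lam**2 * s, s)
        out[i] = sigma * math.pi * R_E**2 * N_A / el.weight
    return out


def energy_grid(symbol: str) -> np.ndarray:
    grid = list(np.geomspace(E_MIN, E_MAX, N_GRID))
    edge = K_EDGES.get(symbol)
    if edge is not None:
        grid += [edge * 0.999, edge * 1.001]
    return np.array(sorted(grid))


def main() -> None:
    outdir = Path(__file__).resolve().parents[1] / "src" / "pcdsim" / "data" / "attenuation"
    outdir.mkdir(parents=True, exist_ok=True)
    for symbol in ELEMENTS:
        el = gemmi.Element(symbol)
        grid = energy_grid(symbol)
        pe = photoelectric(el.atomic_number, el.weight, grid)
        inc = incoherent(el.atomic_number, el.weight, grid)
        coh = coherent(el, grid)
        total = pe + inc + coh
        header = (
            f"mass attenuation coefficients for {symbol} (Z={el.atomic_number}, A={el.weight:.4f})\n"
            f"photoelectric: Cromer-Liberman f'' (gemmi {gemmi.__version__}); "
            "incoherent: Klein-Nishina free-electron; "
            "coherent: Thomson x IT92 form factor\n"
            f"K-edge: {K_EDGES.get(symbol, 'none')} keV\n"
            "columns: energy_keV photoelectric incoherent coherent total  [cm^2/g]"
        )
        data = np.column_stack([grid, pe, inc, coh, total])
        np.savetxt(outdir / f"{symbol}.txt", data, fmt="%.5e", header=header)
        print(f"{symbol}: {len(grid)} grid points -> {outdir / (symbol + '.txt')}")


if __name__ == "__main__":
    main()
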