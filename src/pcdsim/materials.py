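"""Material physics: mass attenuation, transmission, K fluorescence.

Per-element mass attenuation coefficients are bundled as plain-text tables
(``data/attenuation``) split by interaction process (photoelectric,
incoherent, coherent, total) on a logarithmic 1-300 keV grid with extra
points straddling each K edge, so that log-log interpolation never bridges
an absorption edge.  Compound values follow the elemental mixture rule
(mass-fraction-weighted sum of the elemental coefficients).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

PROCESSES = ("total", "photoelectric", "incoherent", "coherent")
_COLUMN = {"photoelectric": 1, "incoherent": 2, "coherent": 3, "total": 4}

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 300.0


class UnknownElementError(KeyError):
    """Raised for an element symbol without a bundled attenuation table."""


class MissingKDataError(KeyError):
    """Raised for an element without bundled K-fluorescence data."""


def _data_root():
    return resources.files("pcdsim") / "data"


@functools.lru_cache(maxsize=None)
def _element_table(symbol: str) -> np.ndarray:
    path = _data_root() / "attenuation" / f"{symbol}.txt"
    try:
        raw = path.read_text()
    except FileNotFoundError:
        raise UnknownElementError(symbol) from None
    return np.loadtxt(raw.splitlines())


@functools.lru_cache(maxsize=None)
def _fluorescence_data() -> dict:
    return yaml.safe_load((_data_root() / "fluorescence.yaml").read_text())


@functools.lru_cache(maxsize=None)
def _materials_registry() -> dict:
    return yaml.safe_load((_data_root() / "materials.yaml").read_text())


@dataclass(frozen=True)
class MaterialSpec:
    """A homogeneous material: element mass fractions and bulk density.

    Mass fractions are normalized to sum to exactly 1 on construction;
    the raw fractions must be strictly positive.
    """

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float = 1.0

    def __post_init__(self):
        if not self.composition:
            raise ValueError("empty composition")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        syms, fracs = zip(*self.composition)
        fracs = np.asarray(fracs, dtype=float)
        if np.any(fracs <= 0):
            raise ValueError("mass fractions must be strictly positive")
        for s in syms:
            _element_table(s)  # raises UnknownElementError early
        fracs = fracs / fracs.sum()
        object.__setattr__(self, "composition", tuple(zip(syms, fracs.tolist())))

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.composition)

    @property
    def mass_fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.composition])


@dataclass(frozen=True)
class KFluorescence:
    """K-shell data for one element: edge, yield and emission lines."""

    element: str
    k_edge_keV: float
    omega_k: float
    lines: tuple[tuple[float, float], ...]  # (energy keV, probability)

    @property
    def line_energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.lines])

    @property
    def line_probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.lines])


def mixture(components: Iterable[tuple[str, float]], name: str = "mixture",
            density: float = 1.0) -> MaterialSpec:
    """Build a material from ``(element symbol, mass fraction)`` pairs.

    Fractions are rescaled to sum to one (they need not on input, e.g. the
    iodine/water lesion composition that sums to 1.0001).
    """
    return MaterialSpec(name=name, composition=tuple(components), density=density)


def get_material(name: str) -> MaterialSpec:
    """Look up a material from the bundled registry (e.g. ``"czt"``)."""
    reg = _materials_registry()
    if name not in reg:
        raise KeyError(f"unknown material {name!r}; available: {sorted(reg)}")
    entry = reg[name]
    return MaterialSpec(name=name,
                        composition=tuple(entry["composition"].items()),
                        density=float(entry["density"]))


def element_mass_attenuation(symbol: str, energy_keV, process: str = "total") -> np.ndarray:
    """Elemental mass attenuation coefficient (cm^2/g), log-log interpolated."""
    if process not in PROCESSES:
        raise ValueError(f"process must be one of {PROCESSES}")
    energy = np.asarray(energy_keV, dtype=float)
    if np.any(energy < ENERGY_MIN_KEV) or np.any(energy > ENERGY_MAX_KEV):
        raise ValueError(
            f"energy outside table range [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
    tab = _element_table(symbol)
    col = tab[:, _COLUMN[process]]
    # coherent/photoelectric columns can be ~0 at high E for H; floor for log
    vals = np.interp(np.log(energy), np.log(tab[:, 0]), np.log(np.maximum(col, 1e-30)))
    out = np.exp(vals)
    if out.ndim == 0:
        return float(out) if out >= 1e-25 else 0.0
    out[out < 1e-25] = 0.0
    return out


def mass_attenuation(material: MaterialSpec, energy_keV, process: str = "total"):
    """Mass attenuation coefficient of a compound (cm^2/g), mixture rule."""
    energy = np.asarray(energy_keV, dtype=float)
    total = np.zeros_like(energy)
    for sym, frac in material.composition:
        total = total + frac * element_mass_attenuation(sym, energy, process)
    return total if total.ndim else float(total)


def linear_attenuation(material: MaterialSpec, energy_keV, process: str = "total"):
    """Linear attenuation coefficient (1/cm)."""
    return mass_attenuation(material, energy_keV, process) * material.density


def transmission(material: MaterialSpec, thickness_mm: float, energy_keV):
    """No-interaction probability through ``thickness_mm`` of material."""
    if thickness_mm < 0:
        raise ValueError("thickness must be >= 0")
    mu = linear_attenuation(material, energy_keV, "total")
    return np.exp(-mu * thickness_mm / 10.0)


def fluorescence(element: str) -> KFluorescence:
    """K-edge, fluorescence yield omega_K and normalized K emission lines."""
    data = _fluorescence_data()
    if element not in data:
        raise MissingKDataError(element)
    entry = data[element]
    energies = [e for e, _ in entry["lines"]]
    weights = np.array([w for _, w in entry["lines"]], dtype=float)
    probs = weights / weights.sum()
    return KFluorescence(
        element=element,
        k_edge_keV=float(entry["k_edge_keV"]),
        omega_k=float(entry["omega_k"]),
        lines=tuple(zip(energies, probs.tolist())),
    )


def k_edge(element: str) -> float | None:
    """K-edge energy in keV, or None if no K data is bundled."""
    data = _fluorescence_data()
    if element in data:
        return float(data[element]["k_edge_keV"])
    return None


@functools.lru_cache(maxsize=None)
def k_shell_fraction(element: str) -> float:
    """Fraction of photoelectric interactions above the K edge that ionize
    the K shell, derived from the jump of the tabulated photoelectric
    coefficient across the edge: 1 - 1/J."""
    edge = k_edge(element)
    if edge is None:
        raise MissingKDataError(element)
    below = element_mass_attenuation(element, edge * 0.998, "photoelectric")
    above = element_mass_attenuation(element, edge * 1.002, "photoelectric")
    jump = above / below
    if jump <= 1.0:
        raise RuntimeError(f"no photoelectric jump found at K edge of {element}")
    return 1.0 - 1.0 / jump
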