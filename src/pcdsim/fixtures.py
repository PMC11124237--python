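"""Deterministic fixtures used across the test suite and examples:
toy spectra and trains, the idealized (perfectly linear) detector, and the
canonical two-pulse event list.
"""

from __future__ import annotations

import numpy as np

from .detector import (CountingConfig, DeltaPulse, DetectorGeometry,
                       DetectorModel, ResolutionModel)
from .materials import get_material
from .pulsetrain import PulseTrain, synthesize
from .spectra import SpectralFluenceRate
from .transport import DepositionEventList


def ideal_detector(behavior: str = "NP") -> DetectorModel:
    """Perfectly linear reference detector: every incident photon is fully
    absorbed in its entry pixel, no energy blur, single-sample pulse."""
    return DetectorModel(
        name="ideal",
        material=get_material("water"),  # unused by the ideal transport
        geometry=DetectorGeometry(pitch_um=500.0, shape=(5, 5),
                                  thickness_mm=2.0, septum_um=0.0),
        resolution=ResolutionModel(0.0),
        pulse=DeltaPulse(),
        counting=CountingConfig(behavior=behavior, tau_pd_ns=1,
                                tau_np_ns=2 if behavior == "NP" else None),
        ideal=True)


def toy_spectrum() -> SpectralFluenceRate:
    """Three-line spectrum (40, 60, 80 keV) with total rate 1e6 mm^-2 s^-1."""
    e = np.arange(1.0, 101.0)
    f = np.zeros_like(e)
    f[[39, 59, 79]] = [2e5, 5e5, 3e5]
    return SpectralFluenceRate(e, f, {"name": "toy"})


def two_pulse_events(separation_ns: float = 5.0,
                     energy_keV: float = 60.0) -> DepositionEventList:
    """Two equal-energy deposits in the center pixel, a few ns apart."""
    geom = DetectorGeometry(pitch_um=500.0, shape=(5, 5), thickness_mm=2.0)
    cx, cy = geom.center_pixel
    return DepositionEventList(
        pixel_x=np.array([cx, cx]), pixel_y=np.array([cy, cy]),
        energy_keV=np.array([energy_keV, energy_keV]),
        time_ns=np.array([100.0, 100.0 + separation_ns]),
        primary=np.array([0, 1]), source=np.zeros(2, dtype=int),
        duration_ns=1000.0, geometry=geom)


def toy_train() -> PulseTrain:
    """The two-pulse event list synthesized with a Gaussian 14 ns pulse,
    blurring disabled."""
    from .detector import GaussianPulse
    ev = two_pulse_events()
    return synthesize(ev, GaussianPulse(14.0), ResolutionModel(0.0),
                      ev.duration_ns, blur=False)


_KINDS = {
    "ideal-detector": ideal_detector,
    "toy-spectrum": toy_spectrum,
    "two-pulse": two_pulse_events,
    "toy-train": toy_train,
}


def make_fixture(kind: str):
    """Build one of the named deterministic fixtures."""
    if kind not in _KINDS:
        raise KeyError(f"unknown fixture kind {kind!r}; options: {sorted(_KINDS)}")
    return _KINDS[kind]()
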