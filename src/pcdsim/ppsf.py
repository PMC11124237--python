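"""Perturbation point spread function estimation.

The pPSF h_k(dn, op, E_l) is the change in registered count rate in energy
bin k and pixel offset dn per incident probe photon of energy E_l, with the
detector held at an operating point (spectrum shape and total fluence
rate).  It is estimated by paired runs: the operating-spectrum realization
is simulated once and reused, a monoenergetic probe on the center pixel is
added, and

    h = (d_perturbed - d_baseline) / (probe fluence rate * pixel area)

is formed for every bin and offset.  Standard errors come from section-wise
replication of the paired difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import (CountRates, SectionedCounts, bin_counts,
                       count_pixel_events, sectioned_counts, CountRecords)
from .detector import DetectorModel
from .pulsetrain import blur_energy
from .spectra import LesionSpec, SpectralFluenceRate
from .transport import (DepositionEventList, ProbeBeam, probe_streams,
                        rng_streams, sample_operating_photons,
                        simulate_exposure, simulate_probe, transport_photons)

DEFAULT_PROBE_GRID = np.arange(20.0, 151.0, 2.0)
PROBE_RATE_CAP = 1e6        # mm^-2 s^-1
PROBE_RATE_FRACTION = 0.05
PROBE_RATE_FLOOR = 1e6      # used at zero operating rate


def default_probe_rate(op_total_rate: float) -> float:
    """Probe fluence rate: 5% of the operating rate, capped at 1e6 mm^-2
    s^-1, with a floor of 1e6 at negligible operating rate (probe
    self-pile-up stays at the percent level for the bundled windows)."""
    if op_total_rate <= PROBE_RATE_FLOOR / PROBE_RATE_FRACTION:
        return PROBE_RATE_FLOOR
    return min(PROBE_RATE_FRACTION * op_total_rate, PROBE_RATE_CAP)


@dataclass
class LinearPSF:
    """Low-rate detector PSF: probability h_k(dn, E_l) of registering a
    count in bin k at offset dn per photon incident at energy E_l."""

    values: np.ndarray  # (n_bins, nx, ny, n_energies)
    bin_centers_keV: np.ndarray
    energies_keV: np.ndarray


@dataclass
class PPSF:
    """Estimated perturbation PSF with standard errors and provenance."""

    values: np.ndarray  # (n_bins, nx, ny, n_energies)
    se: np.ndarray
    bin_centers_keV: np.ndarray
    offsets_x: np.ndarray
    offsets_y: np.ndarray
    probe_energies_keV: np.ndarray
    op_total_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def center_index(self) -> tuple[int, int]:
        return (int(np.flatnonzero(self.offsets_x == 0)[0]),
                int(np.flatnonzero(self.offsets_y == 0)[0]))

    def center_slice(self, probe_energy_keV: float) -> np.ndarray:
        """h over all bins at dn = 0 for one probe energy."""
        cx, cy = self.center_index
        idx = int(np.argmin(np.abs(self.probe_energies_keV - probe_energy_keV)))
        return self.values[:, cx, cy, idx]

    def center_se(self, probe_energy_keV: float) -> np.ndarray:
        cx, cy = self.center_index
        idx = int(np.argmin(np.abs(self.probe_energies_keV - probe_energy_keV)))
        return self.se[:, cx, cy, idx]

    def interp_center(self, energies_keV: np.ndarray) -> np.ndarray:
        """h(k, dn=0) linearly interpolated in probe energy onto the given
        grid; energies outside the probe grid extrapolate as zero."""
        cx, cy = self.center_index
        h = self.values[:, cx, cy, :]
        out = np.zeros((h.shape[0], energies_keV.size))
        inside = ((energies_keV >= self.probe_energies_keV[0])
                  & (energies_keV <= self.probe_energies_keV[-1]))
        for k in range(h.shape[0]):
            out[k, inside] = np.interp(energies_keV[inside],
                                       self.probe_energies_keV, h[k])
        return out

    def contract_center(self, delta_fluence: np.ndarray,
                        energies_keV: np.ndarray, area_mm2: float,
                        all_offsets: bool = True
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Contract the pPSF with a perturbation spectrum.

        For a perturbation that dims the beam homogeneously over the array
        (a lesion in the projection path), the first-order change of the
        center-pixel rate sums the pPSF over all pixel offsets
        (``all_offsets=True``): crosstalk flowing in from the neighbors is
        part of the response.  ``all_offsets=False`` uses dn = 0 only, the
        single-pixel reading without crosstalk.

        Folds the 1 keV perturbation onto the probe grid through the
        transpose of linear interpolation, so the estimator noise is
        propagated at the probe points where it is actually independent.
        Returns (numerator rates, numerator variances) per bin k.
        """
        pe = self.probe_energies_keV
        w = np.zeros(pe.size)
        inside = (energies_keV >= pe[0]) & (energies_keV <= pe[-1])
        e = energies_keV[inside]
        d = np.asarray(delta_fluence)[inside]
        j = np.clip(np.searchsorted(pe, e, side="right") - 1, 0, pe.size - 2)
        lam = (e - pe[j]) / (pe[j + 1] - pe[j])
        np.add.at(w, j, (1.0 - lam) * d)
        np.add.at(w, j + 1, lam * d)
        if all_offsets:
            h = self.values.sum(axis=(1, 2))
            se2 = (self.se**2).sum(axis=(1, 2))
        else:
            cx, cy = self.center_index
            h = self.values[:, cx, cy, :]
            se2 = self.se[:, cx, cy, :] ** 2
        num = (h @ w) * area_mm2
        var = se2 @ (w**2) * area_mm2**2
        return num, var

    def to_frame(self, center_only: bool = True) -> pd.DataFrame:
        """Tidy export (bin, offset, probe energy, h, se)."""
        cx, cy = self.center_index
        rows = []
        xs = [cx] if center_only else range(self.offsets_x.size)
        ys = [cy] if center_only else range(self.offsets_y.size)
        for ix in xs:
            for iy in ys:
                for il, el in enumerate(self.probe_energies_keV):
                    rows.append(pd.DataFrame({
                        "bin_center_keV": self.bin_centers_keV,
                        "offset_x": self.offsets_x[ix],
                        "offset_y": self.offsets_y[iy],
                        "probe_energy_keV": el,
                        "h": self.values[:, ix, iy, il],
                        "se": self.se[:, ix, iy, il]}))
        return pd.concat(rows, ignore_index=True)


def _pixel_event_cache(events: DepositionEventList, energies_blurred,
                       shape) -> dict:
    cache = {}
    for ix in range(shape[0]):
        for iy in range(shape[1]):
            m = (events.pixel_x == ix) & (events.pixel_y == iy)
            cache[ix, iy] = (events.time_ns[m], np.asarray(energies_blurred)[m])
    return cache


def _count_sections(times, energies, detector: DetectorModel,
                    duration_ns: float, n_sections: int) -> np.ndarray:
    """Per-section binned counts (n_sections, n_bins) for one pixel."""
    cfg = detector.counting
    kernel = detector.pulse.kernel()
    tt, ee = count_pixel_events(times, energies, kernel, cfg)
    edges = cfg.bin_edges_keV
    nbins = edges.size - 1
    out = np.zeros((n_sections, nbins), dtype=np.int64)
    if tt.size:
        sec_len = duration_ns / n_sections
        sec = np.clip((tt // sec_len).astype(int), 0, n_sections - 1)
        which = np.digitize(ee, edges) - 1
        keep = (which >= 0) & (which < nbins)
        np.add.at(out, (sec[keep], which[keep]), 1)
    return out


def baseline_rates(detector: DetectorModel, op_spectrum: SpectralFluenceRate,
                   duration_ns: float, seed: int,
                   n_sections: int = 8) -> tuple[CountRates, SectionedCounts]:
    """Registered count rates under homogeneous operating-spectrum
    irradiation; the center-pixel rates serve as the shift-invariant d_k."""
    events = simulate_exposure(op_spectrum, detector, duration_ns, seed)
    rng_blur = np.random.default_rng(rng_streams(seed)["blur"])
    blurred = _blur(events, detector, rng_blur)
    shape = detector.geometry.shape
    cache = _pixel_event_cache(events, blurred, shape)
    nbins = detector.counting.bin_centers_keV.size
    counts = np.zeros((n_sections, shape[0], shape[1], nbins), dtype=np.int64)
    for (ix, iy), (tt, ee) in cache.items():
        counts[:, ix, iy, :] = _count_sections(tt, ee, detector,
                                               duration_ns, n_sections)
    sectioned = SectionedCounts(counts, detector.counting.bin_centers_keV,
                                duration_ns / n_sections)
    return sectioned.summed(), sectioned


def _blur(events: DepositionEventList, detector: DetectorModel, rng):
    if len(events) == 0:
        return np.empty(0)
    if detector.resolution.rel_fwhm_ref == 0:
        return events.energy_keV
    return blur_energy(events.energy_keV, detector.resolution, rng)


def estimate_ppsf(detector: DetectorModel, op_spectrum: SpectralFluenceRate,
                  probe_energies_keV: np.ndarray | None = None,
                  duration_ns: float = 1e6, probe_rate: float | None = None,
                  n_sections: int = 8, seed: int = 0,
                  paired: bool = True) -> PPSF:
    """Estimate the pPSF by a probe-energy sweep at one operating point.

    With ``paired=True`` (default) the operating-spectrum realization is
    common to the baseline and every perturbed run, which cancels most of
    the background Poisson noise from the paired difference.
    ``paired=False`` re-simulates an independent background per probe
    energy (bias checks only; much noisier).
    """
    if probe_energies_keV is None:
        probe_energies_keV = DEFAULT_PROBE_GRID
    probe_energies_keV = np.asarray(probe_energies_keV, dtype=float)
    op_rate = op_spectrum.total_rate
    if probe_rate is None:
        probe_rate = default_probe_rate(op_rate)
    if probe_rate <= 0:
        raise ValueError("probe rate must be > 0")

    geom = detector.geometry
    shape = geom.shape
    area = geom.pixel_area_mm2
    nbins = detector.counting.bin_centers_keV.size
    n_l = probe_energies_keV.size

    bg = simulate_exposure(op_spectrum, detector, duration_ns, seed)
    bg_blurred = _blur(bg, detector, np.random.default_rng(rng_streams(seed)["blur"]))
    cache = _pixel_event_cache(bg, bg_blurred, shape)
    base = {key: _count_sections(tt, ee, detector, duration_ns, n_sections)
            for key, (tt, ee) in cache.items()}

    values = np.zeros((nbins, shape[0], shape[1], n_l))
    se = np.zeros_like(values)
    denom = probe_rate * area * (duration_ns / n_sections) * 1e-9  # photons/section
    for il, el in enumerate(probe_energies_keV):
        streams = probe_streams(seed, il)
        probe = ProbeBeam(el, probe_rate)
        pev = simulate_probe(probe, detector, duration_ns, streams)
        p_blurred = _blur(pev, detector,
                          np.random.default_rng(streams["blur"]))
        if paired:
            affected = set(zip(pev.pixel_x.tolist(), pev.pixel_y.tolist()))
            base_here = base
        else:
            bg_i = simulate_exposure(op_spectrum, detector, duration_ns,
                                     seed + 7919 * (il + 1))
            bg_i_blur = _blur(bg_i, detector, np.random.default_rng(
                rng_streams(seed + 7919 * (il + 1))["blur"]))
            cache_i = _pixel_event_cache(bg_i, bg_i_blur, shape)
            base_here = {k: _count_sections(tt, ee, detector, duration_ns,
                                            n_sections)
                         for k, (tt, ee) in cache_i.items()}
            cache = cache_i
            affected = {(ix, iy) for ix in range(shape[0])
                        for iy in range(shape[1])}
        for (ix, iy) in affected:
            m = (pev.pixel_x == ix) & (pev.pixel_y == iy)
            tt0, ee0 = cache[ix, iy]
            tt = np.concatenate([tt0, pev.time_ns[m]])
            ee = np.concatenate([ee0, np.asarray(p_blurred)[m]])
            pert = _count_sections(tt, ee, detector, duration_ns, n_sections)
            diff = (pert - base_here[ix, iy]) / denom  # per-section h
            values[:, ix, iy, il] = diff.mean(axis=0)
            se[:, ix, iy, il] = diff.std(axis=0, ddof=1) / np.sqrt(n_sections)

    cx, cy = geom.center_pixel
    return PPSF(values=values, se=se,
                bin_centers_keV=detector.counting.bin_centers_keV,
                offsets_x=np.arange(shape[0]) - cx,
                offsets_y=np.arange(shape[1]) - cy,
                probe_energies_keV=probe_energies_keV,
                op_total_rate=op_rate,
                metadata={"duration_ns": duration_ns,
                          "probe_rate_per_mm2_s": probe_rate,
                          "n_sections": n_sections, "seed": seed,
                          "paired": paired,
                          "detector": detector.name,
                          "behavior": detector.counting.behavior})


def paired_lesion_exposure(detector: DetectorModel,
                           op_spectrum: SpectralFluenceRate,
                           lesion: LesionSpec, duration_ns: float,
                           seed: int, n_sections: int = 8
                           ) -> tuple[SectionedCounts, SectionedCounts]:
    """Simulate the lesion-present and lesion-absent exposures as a
    maximally coupled pair and return (target, baseline) sectioned counts.

    The lesion attenuates the baseline spectrum entrywise, so the target
    photon stream is an exact Bernoulli thinning of the baseline stream:
    each baseline photon of energy E survives with probability
    exp(-mu(E)/rho * rho x).  Simulating the baseline once and removing
    the thinned photons (with their deposits and blur draws) realizes both
    exposures on common random numbers, so the contrast estimate is not
    dominated by the shared Poisson noise.
    """
    from .materials import mass_attenuation
    streams = rng_streams(seed)
    times, energies, x, y = sample_operating_photons(
        op_spectrum, detector, duration_ns, streams)
    rng_tr = np.random.default_rng(streams["transport"])
    idx, px, py, e = transport_photons(energies, x, y, detector, rng_tr)
    events = DepositionEventList(px, py, e, times[idx], idx,
                                 np.zeros(idx.size, dtype=int),
                                 duration_ns, detector.geometry)
    blurred = _blur(events, detector,
                    np.random.default_rng(streams["blur"]))
    survive_p = np.exp(-mass_attenuation(lesion.material, energies)
                       * lesion.areal_density_g_cm2)
    rng_thin = np.random.default_rng(streams["thinning"])
    kept = rng_thin.uniform(size=energies.size) < survive_p
    keep_event = kept[events.primary]

    shape = detector.geometry.shape
    nbins = detector.counting.bin_centers_keV.size
    out = []
    for mask in (keep_event, np.ones(len(events), dtype=bool)):
        sel = events.select(mask)
        ee = np.asarray(blurred)[mask]
        counts = np.zeros((n_sections, shape[0], shape[1], nbins),
                          dtype=np.int64)
        for ix in range(shape[0]):
            for iy in range(shape[1]):
                m = (sel.pixel_x == ix) & (sel.pixel_y == iy)
                counts[:, ix, iy, :] = _count_sections(
                    sel.time_ns[m], ee[m], detector, duration_ns, n_sections)
        out.append(SectionedCounts(counts, detector.counting.bin_centers_keV,
                                   duration_ns / n_sections))
    return out[0], out[1]


def linear_response(psf: LinearPSF, spectrum_map: np.ndarray,
                    area_mm2: float) -> np.ndarray:
    """Registered count rates of a linear shift-invariant detector:

        d_k(n) = sum_l sum_n' h_k(n - n', E_l) Phi(n', E_l) * A

    ``spectrum_map`` has shape (nx, ny, n_energies); returns (nx, ny,
    n_bins) rates.
    """
    nbins, hx, hy, n_l = psf.values.shape
    nx, ny, n_l2 = spectrum_map.shape
    if n_l2 != n_l:
        raise ValueError("energy grids of PSF and spectrum map differ")
    # offsets of the PSF are centered
    ox = np.arange(hx) - hx // 2
    oy = np.arange(hy) - hy // 2
    out = np.zeros((nx, ny, nbins))
    for ix in range(nx):
        for iy in range(ny):
            for dx_i, dx in enumerate(ox):
                sx = ix - dx
                if not 0 <= sx < nx:
                    continue
                for dy_i, dy in enumerate(oy):
                    sy = iy - dy
                    if not 0 <= sy < ny:
                        continue
                    out[ix, iy] += psf.values[:, dx_i, dy_i, :] @ \
                        spectrum_map[sx, sy] * area_mm2
    return out
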