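"""Simplified Monte-Carlo photon transport in the pixel array.

A single-scatter-recursive model that preserves the effects the framework
relies on: energy-dependent absorption efficiency, K-fluorescence escape
and crosstalk, Compton-scatter crosstalk, and the reflector dead area of
the indirect-conversion detector.  Electrons have zero range (no charge
sharing), optical transport is omitted, and coherent scattering is ignored
(it deposits no energy; its small angular crosstalk is neglected).

Randomness is organized as named substreams spawned from one master seed:
adding a probe beam never perturbs the operating-spectrum realization,
which is the common-random-numbers guarantee the pPSF estimator relies on.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from . import materials as mat
from .detector import DetectorGeometry, DetectorModel
from .spectra import SpectralFluenceRate

_MAX_SCATTER_DEPTH = 5
_ELECTRON_REST_KEV = 511.0


@dataclass(frozen=True)
class ProbeBeam:
    """Monoenergetic probe irradiating the full pitch of one pixel."""

    energy_keV: float
    rate_per_mm2_s: float
    pixel: tuple[int, int] | None = None  # None -> center pixel


@dataclass
class DepositionEventList:
    """Per-pixel energy deposits: (pixel, energy, time, primary, source)."""

    pixel_x: np.ndarray
    pixel_y: np.ndarray
    energy_keV: np.ndarray
    time_ns: np.ndarray
    primary: np.ndarray
    source: np.ndarray  # 0 = operating spectrum, 1 = probe
    duration_ns: float = 0.0
    geometry: DetectorGeometry | None = None

    def __len__(self):
        return self.energy_keV.size

    def for_pixel(self, ix: int, iy: int) -> tuple[np.ndarray, np.ndarray]:
        m = (self.pixel_x == ix) & (self.pixel_y == iy)
        return self.time_ns[m], self.energy_keV[m]

    def select(self, mask) -> "DepositionEventList":
        return DepositionEventList(
            self.pixel_x[mask], self.pixel_y[mask], self.energy_keV[mask],
            self.time_ns[mask], self.primary[mask], self.source[mask],
            self.duration_ns, self.geometry)

    @staticmethod
    def concatenate(lists: list["DepositionEventList"]) -> "DepositionEventList":
        lists = [l for l in lists if len(l)]
        if not lists:
            raise ValueError("nothing to concatenate")
        return DepositionEventList(
            *(np.concatenate([getattr(l, f) for l in lists])
              for f in ("pixel_x", "pixel_y", "energy_keV", "time_ns",
                        "primary", "source")),
            duration_ns=max(l.duration_ns for l in lists),
            geometry=lists[0].geometry)

    def save_text(self, path) -> None:
        header = ("deposition events\ncolumns: primary pixel_x pixel_y "
                  "energy_keV time_ns source")
        np.savetxt(path, np.column_stack([
            self.primary, self.pixel_x, self.pixel_y,
            self.energy_keV, self.time_ns, self.source]),
            fmt=["%d", "%d", "%d", "%.6e", "%.4f", "%d"], header=header)


def rng_streams(seed: int) -> dict:
    """Named, independent random substreams derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(6)
    names = ("arrivals", "energies", "transport", "blur", "probe", "thinning")
    return dict(zip(names, children))


def probe_streams(seed: int, index: int) -> dict:
    """Independent substreams for the ``index``-th probe configuration."""
    parent = rng_streams(seed)["probe"]
    child = parent.spawn(index + 1)[index]
    arr, tr, blur = child.spawn(3)
    return {"arrivals": arr, "transport": tr, "blur": blur}


def sample_arrivals(rate_per_mm2_s: float, area_mm2: float,
                    duration_ns: float, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson arrival times in [0, duration) ns."""
    if rate_per_mm2_s < 0:
        raise ValueError("rate must be >= 0")
    if duration_ns <= 0:
        raise ValueError("duration must be > 0")
    expected = rate_per_mm2_s * area_mm2 * duration_ns * 1e-9
    n = rng.poisson(expected)
    return np.sort(rng.uniform(0.0, duration_ns, n))


# ---------------------------------------------------------------------------
# cross-section lookups (linear attenuation in 1/um)

@functools.lru_cache(maxsize=None)
def _mu_table(material: mat.MaterialSpec, process: str) -> tuple:
    e = np.geomspace(1.0, 300.0, 600)
    mu = mat.mass_attenuation(material, e, process) * material.density * 1e-4
    return np.log(e), np.log(np.maximum(mu, 1e-300))


def _mu_um(material: mat.MaterialSpec, energy, process: str) -> np.ndarray:
    loge, logmu = _mu_table(material, process)
    return np.exp(np.interp(np.log(np.asarray(energy, float)), loge, logmu))


@functools.lru_cache(maxsize=None)
def _element_pe_shares(material: mat.MaterialSpec) -> tuple:
    """Per-element photoelectric contribution tables for element selection."""
    e = np.geomspace(1.0, 300.0, 600)
    shares = np.stack([
        frac * mat.element_mass_attenuation(sym, e, "photoelectric")
        for sym, frac in material.composition])
    return np.log(e), shares, tuple(material.elements)


@functools.lru_cache(maxsize=None)
def _k_data(element: str):
    try:
        fl = mat.fluorescence(element)
    except mat.MissingKDataError:
        return None
    return (fl.k_edge_keV, mat.k_shell_fraction(element) * fl.omega_k,
            fl.line_energies, np.cumsum(fl.line_probabilities))


def _sample_klein_nishina(energy, rng):
    """Kahn rejection sampling of the Compton scattered-photon energy and
    polar angle; returns (scattered energy, cos theta)."""
    k = np.asarray(energy, float) / _ELECTRON_REST_KEV
    n = k.size
    x = np.empty(n)          # E / E'
    todo = np.ones(n, dtype=bool)
    while todo.any():
        kk = k[todo]
        r1, r2, r3 = rng.uniform(size=(3, kk.size))
        branch = r1 <= (1 + 2 * kk) / (9 + 2 * kk)
        xx = np.where(branch, 1 + 2 * kk * r2, (1 + 2 * kk) / (1 + 2 * kk * r2))
        cos_t = 1 - (xx - 1) / kk
        acc = np.where(branch,
                       r3 <= 4 * (1 / xx - 1 / xx**2),
                       r3 <= 0.5 * (cos_t**2 + 1 / xx))
        idx = np.flatnonzero(todo)
        x[idx[acc]] = xx[acc]
        todo[idx[acc]] = False
    cos_theta = 1 - (x - 1) / k
    return np.asarray(energy, float) / x, cos_theta


def _rotate(direction: np.ndarray, cos_t: np.ndarray,
            phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle acos(cos_t) and azimuth phi."""
    d = direction
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, 1))
    # orthonormal frame (u, v, d)
    helper = np.zeros_like(d)
    use_x = np.abs(d[:, 2]) > 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 2] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return (sin_t * np.cos(phi))[:, None] * u \
        + (sin_t * np.sin(phi))[:, None] * v + cos_t[:, None] * d


def _isotropic(n: int, rng) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    sin_t = np.sqrt(1 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


class _DepositBuffer:
    def __init__(self):
        self.idx, self.x, self.y, self.e = [], [], [], []

    def add(self, idx, x, y, e):
        keep = e > 1e-9
        self.idx.append(np.asarray(idx)[keep])
        self.x.append(np.asarray(x)[keep])
        self.y.append(np.asarray(y)[keep])
        self.e.append(np.asarray(e)[keep])

    def arrays(self):
        if not self.idx:
            z = np.empty(0)
            return z.astype(int), z, z, z
        return (np.concatenate(self.idx).astype(int), np.concatenate(self.x),
                np.concatenate(self.y), np.concatenate(self.e))


def transport_photons(energies: np.ndarray, entry_x_um: np.ndarray,
                      entry_y_um: np.ndarray, detector: DetectorModel,
                      rng: np.random.Generator):
    """Transport a batch of photons entering the sensor surface along +z.

    Returns ``(primary index, pixel_x, pixel_y, deposited energy)`` arrays
    with same-pixel deposits of one primary already merged.
    """
    geom = detector.geometry
    pitch = geom.pitch_um
    nx, ny = geom.shape
    extent = np.array([nx * pitch, ny * pitch, geom.thickness_mm * 1e3])
    material = detector.material
    n = energies.size
    buf = _DepositBuffer()

    if detector.ideal:
        buf.add(np.arange(n), entry_x_um, entry_y_um, energies)
        return _merge(buf, geom, n)

    # reflector dead area: photons entering a septum deposit nothing
    if geom.septum_um > 0:
        fx = np.mod(entry_x_um, pitch)
        fy = np.mod(entry_y_um, pitch)
        s = geom.septum_um
        active = (fx >= s) & (fx < pitch - s) & (fy >= s) & (fy < pitch - s)
    else:
        active = np.ones(n, dtype=bool)

    idx = np.flatnonzero(active)
    pos = np.column_stack([entry_x_um[idx], entry_y_um[idx],
                           np.zeros(idx.size)])
    direction = np.zeros((idx.size, 3))
    direction[:, 2] = 1.0
    e = energies[idx].astype(float)

    for depth in range(_MAX_SCATTER_DEPTH + 1):
        if idx.size == 0:
            break
        mu = _mu_um(material, e, "photoelectric") + _mu_um(material, e, "incoherent")
        step = -np.log(rng.uniform(size=e.size)) / mu
        pos = pos + direction * step[:, None]
        inside = np.all((pos >= 0) & (pos < extent), axis=1)
        idx, pos, direction, e = idx[inside], pos[inside], direction[inside], e[inside]
        if idx.size == 0:
            break
        if depth == _MAX_SCATTER_DEPTH:
            buf.add(idx, pos[:, 0], pos[:, 1], e)  # forced absorption
            break
        pe = _mu_um(material, e, "photoelectric")
        inc = _mu_um(material, e, "incoherent")
        photo = rng.uniform(size=e.size) < pe / (pe + inc)

        # --- photoelectric: local deposit, possibly one K-fluorescence photon
        if photo.any():
            _photoelectric(idx[photo], pos[photo], e[photo], detector,
                           extent, rng, buf)

        # --- incoherent: deposit electron energy, recurse on scattered photon
        sc = ~photo
        idx, pos, direction, e_in = idx[sc], pos[sc], direction[sc], e[sc]
        if idx.size:
            e_out, cos_t = _sample_klein_nishina(e_in, rng)
            buf.add(idx, pos[:, 0], pos[:, 1], e_in - e_out)
            phi = rng.uniform(0.0, 2 * np.pi, idx.size)
            direction = _rotate(direction, cos_t, phi)
            e = e_out
        else:
            e = e_in

    return _merge(buf, geom, n)


def _photoelectric(idx, pos, e, detector, extent, rng, buf):
    material = detector.material
    loge, shares, elements = _element_pe_shares(material)
    share_here = np.stack([np.interp(np.log(e), loge, s) for s in shares])
    cum = np.cumsum(share_here, axis=0)
    u = rng.uniform(size=e.size) * cum[-1]
    which = (u[None, :] > cum).sum(axis=0)

    local = e.copy()
    for ei, sym in enumerate(elements):
        kdat = _k_data(sym)
        m = which == ei
        if not m.any() or kdat is None:
            continue
        edge, p_kfluor, line_e, line_cum = kdat
        cand = m & (e > edge)
        if not cand.any():
            continue
        emit = cand & (rng.uniform(size=e.size) < p_kfluor)
        ne = int(emit.sum())
        if ne == 0:
            continue
        lines = line_e[np.searchsorted(line_cum, rng.uniform(size=ne))]
        local[emit] = e[emit] - lines
        # transport the K photon: isotropic, exponential path, full local
        # absorption at its endpoint (or escape)
        d = _isotropic(ne, rng)
        mu_l = _mu_um(material, lines, "photoelectric") \
            + _mu_um(material, lines, "incoherent")
        end = pos[emit] + d * (-np.log(rng.uniform(size=ne)) / mu_l)[:, None]
        ins = np.all((end >= 0) & (end < extent), axis=1)
        if ins.any():
            buf.add(idx[emit][ins], end[ins, 0], end[ins, 1], lines[ins])
    buf.add(idx, pos[:, 0], pos[:, 1], local)


def _merge(buf: _DepositBuffer, geom: DetectorGeometry, n_primaries: int):
    idx, x, y, e = buf.arrays()
    if idx.size == 0:
        z = np.empty(0)
        return z.astype(int), z.astype(int), z.astype(int), z
    pitch = geom.pitch_um
    px = np.clip((x // pitch).astype(int), 0, geom.shape[0] - 1)
    py = np.clip((y // pitch).astype(int), 0, geom.shape[1] - 1)
    key = (idx * geom.shape[0] + px) * geom.shape[1] + py
    order = np.argsort(key, kind="stable")
    key, e = key[order], e[order]
    first = np.concatenate([[True], key[1:] != key[:-1]])
    starts = np.flatnonzero(first)
    e_merged = np.add.reduceat(e, starts)
    key_u = key[first]
    py_u = key_u % geom.shape[1]
    px_u = (key_u // geom.shape[1]) % geom.shape[0]
    idx_u = key_u // (geom.shape[0] * geom.shape[1])
    return idx_u.astype(int), px_u.astype(int), py_u.astype(int), e_merged


def interact(energy_keV: float, entry_point_um, detector: DetectorModel,
             rng: np.random.Generator) -> list[dict]:
    """Transport a single photon; returns one dict per deposit."""
    i, px, py, e = transport_photons(
        np.array([float(energy_keV)]),
        np.array([float(entry_point_um[0])]),
        np.array([float(entry_point_um[1])]), detector, rng)
    return [{"pixel": (int(a), int(b)), "energy_keV": float(v)}
            for a, b, v in zip(px, py, e)]


def _sample_energies(spec: SpectralFluenceRate, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    p = spec.fluence / spec.fluence.sum()
    cdf = np.cumsum(p)
    return spec.energies_keV[np.searchsorted(cdf, rng.uniform(size=n))]


def sample_operating_photons(spec: SpectralFluenceRate,
                             detector: DetectorModel, duration_ns: float,
                             streams: dict):
    """Draw the primary photons of a homogeneous operating-spectrum
    exposure: (times, energies, x, y)."""
    geom = detector.geometry
    area = geom.pixel_area_mm2 * geom.shape[0] * geom.shape[1]
    rng_arr = np.random.default_rng(streams["arrivals"])
    rng_en = np.random.default_rng(streams["energies"])
    times = sample_arrivals(spec.total_rate, area, duration_ns, rng_arr)
    n = times.size
    energies = _sample_energies(spec, n, rng_en)
    x = rng_en.uniform(0.0, geom.shape[0] * geom.pitch_um, n)
    y = rng_en.uniform(0.0, geom.shape[1] * geom.pitch_um, n)
    return times, energies, x, y


def simulate_exposure(spec: SpectralFluenceRate, detector: DetectorModel,
                      duration_ns: float, seed: int,
                      probe: ProbeBeam | None = None) -> DepositionEventList:
    """Irradiate the whole array homogeneously with the operating spectrum
    and, optionally, add a monoenergetic probe beam on one pixel.

    The operating-spectrum realization depends only on (seed, spectrum,
    duration): the probe uses independent substreams, so adding it does not
    perturb the background (common random numbers across paired runs).
    """
    streams = rng_streams(seed)
    parts = []
    geom = detector.geometry
    total = spec.total_rate
    if total > 0:
        times, energies, x, y = sample_operating_photons(
            spec, detector, duration_ns, streams)
        rng_tr = np.random.default_rng(streams["transport"])
        idx, px, py, e = transport_photons(energies, x, y, detector, rng_tr)
        parts.append(DepositionEventList(
            px, py, e, times[idx], idx, np.zeros(idx.size, dtype=int),
            duration_ns, geom))
    if probe is not None:
        parts.append(simulate_probe(probe, detector, duration_ns,
                                    probe_streams(seed, 0)))
    if not parts:
        z = np.empty(0)
        return DepositionEventList(z.astype(int), z.astype(int), z, z,
                                   z.astype(int), z.astype(int),
                                   duration_ns, geom)
    return DepositionEventList.concatenate(parts) if len(parts) > 1 else parts[0]


def simulate_probe(probe: ProbeBeam, detector: DetectorModel,
                   duration_ns: float, streams: dict) -> DepositionEventList:
    """Probe-only exposure: photons enter the full pitch of one pixel."""
    geom = detector.geometry
    pixel = probe.pixel if probe.pixel is not None else geom.center_pixel
    if not (0 <= pixel[0] < geom.shape[0] and 0 <= pixel[1] < geom.shape[1]):
        raise ValueError(f"probe pixel {pixel} outside array {geom.shape}")
    rng_arr = np.random.default_rng(streams["arrivals"])
    rng_tr = np.random.default_rng(streams["transport"])
    times = sample_arrivals(probe.rate_per_mm2_s, geom.pixel_area_mm2,
                            duration_ns, rng_arr)
    n = times.size
    x = rng_arr.uniform(pixel[0] * geom.pitch_um, (pixel[0] + 1) * geom.pitch_um, n)
    y = rng_arr.uniform(pixel[1] * geom.pitch_um, (pixel[1] + 1) * geom.pitch_um, n)
    energies = np.full(n, float(probe.energy_keV))
    idx, px, py, e = transport_photons(energies, x, y, detector, rng_tr)
    return DepositionEventList(px, py, e, times[idx], idx,
                               np.ones(idx.size, dtype=int), duration_ns,
                               geom)
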