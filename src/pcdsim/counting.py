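"""Counting behaviors: P-like and NP-like pulse processing, energy binning,
sectioned counting, and the classic analytic dead-time formulas.

NP-like counting opens a fixed analysis window tau_np at the first upward
threshold crossing; the registered energy is the signal maximum over the
first tau_pd of the window, one count per window, and a new window requires
a fresh upward crossing after the previous window has closed.  P-like
counting registers one count (max over tau_pd) per upward crossing; a
prolonged above-threshold excursion therefore yields no further counts
until the signal falls below threshold, which is the paralyzable character.
An upward crossing is sample[t-1] < threshold <= sample[t].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .detector import CountingConfig
from .pulsetrain import PulseTrain, add_pulses


@dataclass
class CountRecords:
    """Registered counts: pixel, trigger time and registered energy."""

    pixel_x: np.ndarray
    pixel_y: np.ndarray
    time_ns: np.ndarray
    energy_keV: np.ndarray

    def __len__(self):
        return self.time_ns.size


@dataclass
class CountRates:
    """Binned counts and rates per pixel."""

    counts: np.ndarray  # (nx, ny, n_bins)
    bin_centers_keV: np.ndarray
    duration_ns: float

    @property
    def rates(self) -> np.ndarray:
        """Counts per second, per pixel and energy bin."""
        return self.counts / (self.duration_ns * 1e-9)

    def center_pixel_rates(self) -> np.ndarray:
        nx, ny = self.counts.shape[:2]
        return self.rates[nx // 2, ny // 2]

    def mean_pixel_rates(self) -> np.ndarray:
        """Per-bin rates averaged over the (homogeneously irradiated)
        array, valid under shift invariance."""
        return self.rates.mean(axis=(0, 1))

    def total_rate(self) -> float:
        return float(self.rates.sum())


@dataclass
class SectionedCounts:
    """Counts resolved into consecutive time sections (for variance)."""

    counts: np.ndarray  # (n_sections, nx, ny, n_bins)
    bin_centers_keV: np.ndarray
    section_length_ns: float

    @property
    def n_sections(self) -> int:
        return self.counts.shape[0]

    @property
    def rates(self) -> np.ndarray:
        return self.counts / (self.section_length_ns * 1e-9)

    def summed(self) -> CountRates:
        return CountRates(self.counts.sum(axis=0), self.bin_centers_keV,
                          self.n_sections * self.section_length_ns)


def _window_max(signal: np.ndarray, width: int) -> np.ndarray:
    """m[t] = max signal over [t, t + width)."""
    padded = np.concatenate([signal, np.zeros(width)])
    filt = maximum_filter1d(padded, size=width, mode="constant", cval=0.0)
    return filt[width // 2:width // 2 + signal.size]


def _scan_samples(signal: np.ndarray, cfg: CountingConfig,
                  t_offset: float = 0.0):
    """Count one pixel's sampled signal; times are sample indices plus
    ``t_offset``."""
    thr = cfg.threshold_keV
    above = signal >= thr
    if not above.any():
        return np.empty(0), np.empty(0)
    up = above.copy()
    up[1:] &= ~above[:-1]
    crossings = np.flatnonzero(up)
    peak = _window_max(signal, int(cfg.tau_pd_ns))
    if cfg.behavior == "P":
        times = crossings
    else:
        tau_np = int(cfg.tau_np_ns)
        # next admissible crossing after each window, precomputed in bulk
        jumps = np.searchsorted(crossings, crossings + tau_np, side="left")
        sel = []
        i = 0
        n = crossings.size
        while i < n:
            sel.append(i)
            i = jumps[i]
        times = crossings[sel]
    return times.astype(float) + t_offset, peak[times]


def count_train(train: PulseTrain, cfg: CountingConfig) -> CountRecords:
    """Run the configured counting behavior over a whole pulse train."""
    px, py, tt, ee = [], [], [], []
    nx, ny = train.signals.shape[:2]
    for ix in range(nx):
        for iy in range(ny):
            t, e = _scan_samples(train.signals[ix, iy], cfg,
                                 t_offset=-train.pad_ns)
            px.append(np.full(t.size, ix))
            py.append(np.full(t.size, iy))
            tt.append(t)
            ee.append(e)
    return CountRecords(np.concatenate(px).astype(int),
                        np.concatenate(py).astype(int),
                        np.concatenate(tt), np.concatenate(ee))


def count_np(train: PulseTrain, cfg: CountingConfig) -> CountRecords:
    if cfg.behavior != "NP" or cfg.tau_np_ns is None:
        raise ValueError("count_np requires an NP-like configuration")
    return count_train(train, cfg)


def count_p(train: PulseTrain, cfg: CountingConfig) -> CountRecords:
    if cfg.behavior != "P":
        raise ValueError("count_p requires a P-like configuration")
    return count_train(train, cfg)


def count_pixel_events(times_ns: np.ndarray, energies_keV: np.ndarray,
                       kernel: np.ndarray, cfg: CountingConfig,
                       kernel_peak: float | None = None):
    """Count one pixel directly from its (blurred) deposition events.

    Events are clustered by gaps long enough that no pulse tail or counting
    window can bridge them; isolated events take an analytic fast path and
    only clusters with overlapping pulses are synthesized as waveforms.  If
    the clusters cover most of the span anyway (heavy pile-up), a single
    dense waveform is scanned instead.  Equivalent to counting the densely
    synthesized train (property-tested).
    """
    if times_ns.size == 0:
        return np.empty(0), np.empty(0)
    if kernel_peak is None:
        kernel_peak = float(kernel.max())
    tau = int(cfg.tau_np_ns if cfg.behavior == "NP" else cfg.tau_pd_ns)
    gap = kernel.size + tau + 2
    order = np.argsort(times_ns, kind="stable")
    t = np.rint(times_ns[order]).astype(np.int64)
    e = np.asarray(energies_keV, dtype=float)[order]
    new_cluster = np.concatenate([[True], np.diff(t) >= gap])
    starts = np.flatnonzero(new_cluster)
    ends = np.concatenate([starts[1:], [t.size]])

    span = int(t[-1] - t[0])
    # per-cluster bookkeeping costs ~the same as scanning ~1000 dense
    # samples, so beyond one cluster per 1000 ns a single scan wins
    if starts.size > 64 and starts.size > span / 1000:
        # dense fallback: one waveform for the whole span
        t0 = t[0]
        sig = np.zeros(span + 2 * kernel.size + tau + 2)
        add_pulses(sig, (t - t0).astype(float), e, kernel, 0)
        return _scan_samples(sig, cfg, t_offset=float(t0))

    single = (ends - starts) == 1

    out_t, out_e = [], []
    # fast path: isolated single events
    si = starts[single]
    if si.size:
        es, ts = e[si], t[si]
        trig = es * kernel_peak >= cfg.threshold_keV
        if trig.any():
            es, ts = es[trig], ts[trig]
            # trigger time: first kernel sample reaching threshold
            reach = es[:, None] * kernel[None, :] >= cfg.threshold_keV
            first = reach.argmax(axis=1)
            out_t.append(ts + first)
            out_e.append(es * kernel_peak)
    # slow path: synthesize each multi-event cluster locally
    for s, end in zip(starts[~single], ends[~single]):
        t0 = t[s]
        length = int(t[end - 1] - t0) + kernel.size + tau + 2
        sig = np.zeros(length + kernel.size)
        add_pulses(sig, (t[s:end] - t0).astype(float), e[s:end], kernel, 0)
        tt, ee = _scan_samples(sig, cfg, t_offset=float(t0))
        out_t.append(tt)
        out_e.append(ee)
    if not out_t:
        return np.empty(0), np.empty(0)
    tt = np.concatenate(out_t).astype(float)
    ee = np.concatenate(out_e)
    order = np.argsort(tt, kind="stable")
    return tt[order], ee[order]


def bin_counts(records: CountRecords, cfg: CountingConfig,
               duration_ns: float, shape: tuple[int, int]) -> CountRates:
    """Histogram registered energies into the configured bins; energies
    outside the bin range are discarded."""
    edges = cfg.bin_edges_keV
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    nbins = edges.size - 1
    counts = np.zeros((shape[0], shape[1], nbins), dtype=np.int64)
    if len(records):
        which = np.digitize(records.energy_keV, edges) - 1
        keep = (which >= 0) & (which < nbins) \
            & (records.energy_keV < edges[-1])
        np.add.at(counts, (records.pixel_x[keep], records.pixel_y[keep],
                           which[keep]), 1)
    return CountRates(counts, cfg.bin_centers_keV, duration_ns)


def sectioned_counts(records: CountRecords, cfg: CountingConfig,
                     duration_ns: float, section_length_ns: float,
                     shape: tuple[int, int]) -> SectionedCounts:
    """Assign counts to consecutive sections by trigger time."""
    n_sections = int(duration_ns // section_length_ns)
    if n_sections < 2:
        raise ValueError("section length must give at least 2 sections")
    edges = cfg.bin_edges_keV
    nbins = edges.size - 1
    counts = np.zeros((n_sections, shape[0], shape[1], nbins), dtype=np.int64)
    if len(records):
        sec = (records.time_ns // section_length_ns).astype(int)
        which = np.digitize(records.energy_keV, edges) - 1
        keep = (which >= 0) & (which < nbins) & (sec >= 0) & (sec < n_sections)
        np.add.at(counts, (sec[keep], records.pixel_x[keep],
                           records.pixel_y[keep], which[keep]), 1)
    return SectionedCounts(counts, cfg.bin_centers_keV, section_length_ns)


def analytic_rate(behavior: str, true_rate_per_s: float,
                  dead_time_s: float) -> float:
    """Classic dead-time count-rate models: NP: n/(1+n tau); P: n e^(-n tau)."""
    if dead_time_s < 0:
        raise ValueError("dead time must be >= 0")
    if true_rate_per_s < 0:
        raise ValueError("rate must be >= 0")
    n, tau = true_rate_per_s, dead_time_s
    if behavior == "NP":
        return n / (1.0 + n * tau)
    if behavior == "P":
        return n * np.exp(-n * tau)
    raise ValueError("behavior must be 'NP' or 'P'")
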