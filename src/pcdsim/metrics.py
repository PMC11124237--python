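"""Contrast and contrast-to-noise metrics for a single projection line.

Contrast per energy bin k is C_k = (d_k(target) - d_k(baseline)) /
d_k(baseline); under the small-signal approximation it is obtained from
the pPSF as C_k = sum_l h_k(dn=0, E_l) * A * dPhi(E_l) / d_k.  CNR divides
the contrast by sigma(C_k) = sqrt(Var(d_k)) / d_k, where the variance is
the per-section sample variance of the baseline bin rates and sections are
sized so every section sees the same dose regardless of fluence rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counting import CountRates, SectionedCounts
from .materials import mass_attenuation
from .ppsf import PPSF
from .spectra import LesionSpec, PerturbationSpectrum


@dataclass
class ContrastResult:
    """Per-bin contrast with optional noise terms.

    ``numerator`` (the bin-rate change) and ``denominator`` (the baseline
    bin rate) are kept so macro-bin rebinning can recompute contrast from
    summed rates instead of averaging contrasts.  Bins with zero baseline
    are masked, never dropped.
    """

    bin_centers_keV: np.ndarray
    numerator: np.ndarray
    denominator: np.ndarray
    sigma: np.ndarray | None = None
    cnr: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def masked(self) -> np.ndarray:
        return self.denominator == 0

    @property
    def contrast(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = self.numerator / self.denominator
        c[self.masked] = np.nan
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_keV": self.bin_centers_keV,
            "contrast": self.contrast,
            "sigma": np.full_like(self.bin_centers_keV, np.nan)
            if self.sigma is None else self.sigma,
            "cnr": np.full_like(self.bin_centers_keV, np.nan)
            if self.cnr is None else self.cnr,
            "masked": self.masked})


def contrast_direct(d_target: CountRates, d_baseline: CountRates,
                    pool_pixels: bool = False) -> ContrastResult:
    """Direct two-run contrast (d_t - d_b)/d_b from measured rates.

    Uses the center pixel by default; ``pool_pixels=True`` averages over
    the homogeneously irradiated array for better statistics.
    """
    if not np.array_equal(d_target.bin_centers_keV, d_baseline.bin_centers_keV):
        raise ValueError("binning mismatch between target and baseline")
    if pool_pixels:
        dt = d_target.mean_pixel_rates()
        db = d_baseline.mean_pixel_rates()
    else:
        dt = d_target.center_pixel_rates()
        db = d_baseline.center_pixel_rates()
    return ContrastResult(d_baseline.bin_centers_keV, dt - db, db,
                          metadata={"method": "direct"})


def contrast_smallsignal(ppsf: PPSF, baseline: CountRates | np.ndarray,
                         perturbation: PerturbationSpectrum,
                         area_mm2: float,
                         all_offsets: bool = True) -> ContrastResult:
    """First-order contrast from the pPSF:

        C_k = sum_dn sum_l h_k(dn, E_l) * A * dPhi(E_l) / d_k

    The perturbation dims the beam over the whole array, so the response
    sums the pPSF over pixel offsets by default (``all_offsets=False``
    restricts to dn = 0, dropping the crosstalk flowing in from the
    neighbors; the difference is visible in fluorescence-fed low-energy
    bins).  h is interpolated linearly from the probe grid onto the 1 keV
    spectrum grid; perturbation entries below the probe grid (below the
    trigger threshold) are truncated to zero.
    """
    if not perturbation.within_small_signal:
        warnings.warn("perturbation exceeded the small-signal threshold; "
                      "the first-order contrast may be biased", stacklevel=2)
    db = baseline.center_pixel_rates() if isinstance(baseline, CountRates) \
        else np.asarray(baseline, dtype=float)
    energies = perturbation.energies_keV
    delta = perturbation.delta_fluence
    if energies[-1] > ppsf.probe_energies_keV[-1] + 1e-9:
        above = energies > ppsf.probe_energies_keV[-1]
        if np.abs(delta[above]).sum() > 0:
            warnings.warn("perturbation support extends above the probe "
                          "grid; contributions there are truncated",
                          stacklevel=2)
    num, var = ppsf.contract_center(delta, energies, area_mm2,
                                    all_offsets=all_offsets)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.sqrt(var) / db
    sigma[db == 0] = np.nan
    return ContrastResult(ppsf.bin_centers_keV, num, db, sigma=sigma,
                          metadata={"method": "small-signal",
                                    "op_total_rate": ppsf.op_total_rate})


def linear_reference_contrast(lesion: LesionSpec, energies_keV) -> np.ndarray:
    """Contrast of a perfectly linear detector: exp(-mu/rho * rho x) - 1,
    independent of fluence rate."""
    mu = mass_attenuation(lesion.material, energies_keV)
    return np.exp(-mu * lesion.areal_density_g_cm2) - 1.0


def equal_dose_section_length(total_rate: float, reference_rate: float = 1e6,
                              reference_length_ns: float = 1e6) -> float:
    """Section length inversely proportional to fluence rate, so each
    section integrates the same dose."""
    if total_rate <= 0:
        raise ValueError("total rate must be > 0")
    return reference_length_ns * reference_rate / total_rate


def cnr(result: ContrastResult, baseline_sections: SectionedCounts,
        pool_pixels: bool = True) -> ContrastResult:
    """Attach sigma(C_k) and CNR_k to a contrast result.

    sigma(C_k) = sqrt(Var(d_k)) / mean(d_k) with the variance taken over
    the per-section baseline bin rates (center pixel, or pooled over all
    pixels of the homogeneously irradiated array).
    """
    if baseline_sections.n_sections < 2:
        raise ValueError("need at least 2 sections for a variance")
    rates = baseline_sections.rates  # (S, nx, ny, K)
    if pool_pixels:
        samples = rates.reshape(-1, rates.shape[-1])
    else:
        nx, ny = rates.shape[1:3]
        samples = rates[:, nx // 2, ny // 2, :]
    var = samples.var(axis=0, ddof=1)
    mean = samples.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.sqrt(var) / mean
        c = result.contrast
        cnr_vals = c / sigma
    bad = (mean == 0) | (var == 0)
    sigma[bad] = np.nan
    cnr_vals[bad] = np.nan
    return replace(result, sigma=sigma, cnr=cnr_vals)


def rebin_macro(obj, macro_edges_keV):
    """Rebin counts or contrast onto macro energy bins.

    Counts are summed; contrast is recomputed from the summed numerator
    and denominator (never averaged), which is what makes contrast
    cancellation and inversion between micro bins visible.
    """
    edges = np.asarray(macro_edges_keV, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("macro edges must be strictly increasing")
    if isinstance(obj, CountRates):
        which = np.digitize(obj.bin_centers_keV, edges) - 1
        nmac = edges.size - 1
        counts = np.zeros(obj.counts.shape[:-1] + (nmac,),
                          dtype=obj.counts.dtype)
        for k in range(nmac):
            counts[..., k] = obj.counts[..., which == k].sum(axis=-1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return CountRates(counts, centers, obj.duration_ns)
    if isinstance(obj, ContrastResult):
        which = np.digitize(obj.bin_centers_keV, edges) - 1
        nmac = edges.size - 1
        num = np.zeros(nmac)
        den = np.zeros(nmac)
        sig = np.zeros(nmac) if obj.sigma is not None else None
        for k in range(nmac):
            m = which == k
            num[k] = obj.numerator[m].sum()
            den[k] = obj.denominator[m].sum()
            if sig is not None:
                # numerator errors treated as independent across micro bins
                err = np.nansum((obj.sigma[m] * obj.denominator[m]) ** 2)
                sig[k] = np.sqrt(err) / den[k] if den[k] > 0 else np.nan
        centers = 0.5 * (edges[:-1] + edges[1:])
        cnr_vals = None
        if obj.cnr is not None and sig is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                cnr_vals = (num / den) / sig
        return ContrastResult(centers, num, den, sigma=sig, cnr=cnr_vals,
                              metadata=dict(obj.metadata, macro=True))
    raise TypeError(f"cannot rebin object of type {type(obj)!r}")
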