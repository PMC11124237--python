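import numpy as np
import pytest

from pcdsim import spectra
from pcdsim.counting import CountRates, SectionedCounts
from pcdsim.fixtures import ideal_detector
from pcdsim.materials import get_material, mass_attenuation
from pcdsim.metrics import (ContrastResult, cnr, contrast_direct,
                            contrast_smallsignal, equal_dose_section_length,
                            linear_reference_contrast, rebin_macro)
from pcdsim.ppsf import PPSF, baseline_rates, estimate_ppsf
from pcdsim.spectra import LesionSpec, lesion_perturbation, rescale_total


def rates_from(vec, duration_ns=1e6):
    counts = np.zeros((5, 5, len(vec)), dtype=np.int64)
    counts[2, 2, :] = vec
    return CountRates(counts, np.arange(20.0, 20.0 + len(vec)), duration_ns)


class TestContrastDirect:
    def test_equal_rates_zero_contrast(self):
        d = rates_from([10, 20, 30])
        c = contrast_direct(d, d)
        assert np.allclose(c.contrast, 0.0)

    def test_uniform_one_percent_drop(self):
        db = rates_from([1000, 2000, 4000])
        dt = rates_from([990, 1980, 3960])
        c = contrast_direct(dt, db)
        assert np.allclose(c.contrast, -0.01)

    def test_zero_baseline_masked(self):
        db = rates_from([100, 0, 100])
        dt = rates_from([90, 5, 90])
        c = contrast_direct(dt, db)
        assert c.masked[1]
        assert np.isnan(c.contrast[1])
        assert not np.isnan(c.contrast[0])

    def test_binning_mismatch(self):
        a = rates_from([1, 2, 3])
        b = CountRates(np.zeros((5, 5, 2), dtype=np.int64),
                       np.array([20.0, 21.0]), 1e6)
        with pytest.raises(ValueError):
            contrast_direct(a, b)


class TestContrastSmallSignal:
    def make_ppsf(self, nbins=231):
        # diagonal pPSF on a coarse probe grid
        pe = np.arange(20.0, 131.0, 2.0)
        vals = np.zeros((nbins, 5, 5, pe.size))
        for i, el in enumerate(pe):
            vals[int(el) - 20, 2, 2, i] = 1.0
        return PPSF(vals, np.zeros_like(vals), np.arange(20.0, 251.0),
                    np.arange(5) - 2, np.arange(5) - 2, pe, 0.0)

    def test_zero_perturbation(self, rqa9):
        h = self.make_ppsf()
        db = np.ones(231)
        pert = lesion_perturbation(rqa9, LesionSpec(
            get_material("iodine_water_lesion"), 0.0))
        c = contrast_smallsignal(h, db, pert, 0.25)
        assert np.allclose(c.numerator, 0.0)

    def test_linear_in_perturbation(self, rqa9):
        h = self.make_ppsf()
        db = np.ones(231)
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0003)
        p1 = lesion_perturbation(rqa9, lesion)
        from dataclasses import replace
        p2 = replace(p1, delta_fluence=2.0 * p1.delta_fluence)
        c1 = contrast_smallsignal(h, db, p1, 0.25)
        c2 = contrast_smallsignal(h, db, p2, 0.25)
        assert np.allclose(c2.numerator, 2.0 * c1.numerator)

    def test_truncation_below_probe_grid(self, rqa9):
        """Perturbation entries below 20 keV must not contribute."""
        h = self.make_ppsf()
        db = np.ones(231)
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0007)
        pert = lesion_perturbation(rescale_total(rqa9, 1e8), lesion)
        c = contrast_smallsignal(h, db, pert, 0.25)
        from dataclasses import replace
        chopped = pert.delta_fluence.copy()
        chopped[:19] = 0.0
        c2 = contrast_smallsignal(h, db, replace(pert, delta_fluence=chopped),
                                  0.25)
        assert np.allclose(c.numerator, c2.numerator)


class TestLinearReference:
    def test_zero_lesion(self):
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0)
        assert np.allclose(linear_reference_contrast(lesion, np.arange(20., 121.)), 0.0)

    def test_strictly_negative(self):
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0007)
        c = linear_reference_contrast(lesion, np.arange(20.0, 121.0))
        assert np.all(c < 0.0)

    def test_closed_form(self):
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0007)
        mu = mass_attenuation(lesion.material, 80.0)
        assert linear_reference_contrast(lesion, np.array([80.0]))[0] == \
            pytest.approx(np.exp(-mu * 0.0007) - 1.0)

    def test_ideal_detector_contrast_matches_attenuation_curve(self):
        """End-to-end: the ideal linear detector's measured small-signal
        contrast follows exp(-mu rho x) - 1 and is rate independent."""
        det = ideal_detector()
        lesion = LesionSpec(get_material("iodine_water_lesion"), 0.0007)
        results = []
        for rate in (1e6, 1e7):
            op = rescale_total(spectra.rqa9_spectrum(), rate)
            d, _ = baseline_rates(det, op, 2e6, seed=31, n_sections=2)
            h = estimate_ppsf(det, op, np.arange(40.0, 121.0, 10.0),
                              duration_ns=4e6, seed=31)
            pert = lesion_perturbation(op, lesion)
            c = contrast_smallsignal(h, d, pert, 0.25)
            results.append(c)
        ref = linear_reference_contrast(lesion, np.arange(20.0, 251.0))
        for c in results:
            # compare where the baseline is well populated (50-110 keV)
            sel = slice(30, 91)
            good = ~c.masked[sel]
            meas = c.contrast[sel][good]
            assert np.nanmedian(np.abs(meas - ref[sel][good])) < 3e-3


class TestCNR:
    def make_sections(self, lam, n_sections, seed=0, nbins=3):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam, size=(n_sections, 5, 5, nbins))
        return SectionedCounts(counts, np.arange(20.0, 20.0 + nbins), 1e4)

    def test_equal_dose_rule(self):
        # 10x the rate -> 10x shorter sections -> equal expected dose
        assert equal_dose_section_length(1e7, 1e6, 1e6) == pytest.approx(1e5)
        assert equal_dose_section_length(1e6, 1e6, 1e6) == 1e6

    def test_sigma_is_sqrt_var_over_mean(self):
        sec = self.make_sections(100.0, 400)
        base = ContrastResult(sec.bin_centers_keV, np.full(3, -1.0),
                              np.full(3, 100.0))
        out = cnr(base, sec)
        # Poisson: sqrt(Var)/mean ~ 1/sqrt(lam)
        assert np.allclose(out.sigma, 0.1, rtol=0.1)
        assert np.allclose(out.cnr, base.contrast / out.sigma,
                           equal_nan=True)

    def test_more_sections_leave_cnr_unbiased(self):
        base = ContrastResult(np.arange(20.0, 23.0), np.full(3, -1.0),
                              np.full(3, 100.0))
        small = cnr(base, self.make_sections(100.0, 100, seed=1))
        big = cnr(base, self.make_sections(100.0, 1000, seed=2))
        assert np.allclose(small.sigma, big.sigma, rtol=0.2)

    def test_cnr_constant_across_rates_at_equal_dose(self):
        """Poisson oracle: with equal dose per section the per-bin CNR of a
        linear detector is invariant under a 100x rate sweep."""
        cnrs = []
        for rate, seed in ((1e6, 3), (1e8, 4)):
            lam = 50.0  # equal dose: same expected counts per section
            sec = self.make_sections(lam, 500, seed=seed)
            base = ContrastResult(sec.bin_centers_keV, np.full(3, -1.0),
                                  np.full(3, 100.0))
            cnrs.append(cnr(base, sec).cnr)
        assert np.allclose(cnrs[0], cnrs[1], rtol=0.15)

    def test_too_few_sections(self):
        sec = self.make_sections(10.0, 1)
        base = ContrastResult(sec.bin_centers_keV, np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            cnr(base, sec)


class TestRebinMacro:
    def test_single_macro_bin_equals_total(self):
        c = ContrastResult(np.arange(20.0, 25.0),
                           np.array([-1.0, -2.0, 3.0, -0.5, 0.5]),
                           np.array([10.0, 20.0, 30.0, 5.0, 5.0]))
        m = rebin_macro(c, [19.5, 24.5])
        assert m.contrast[0] == pytest.approx(0.0 / 70.0)

    def test_cancellation(self):
        # equal and opposite rate changes cancel when merged
        c = ContrastResult(np.array([20.0, 21.0]),
                           np.array([-5.0, 5.0]), np.array([50.0, 100.0]))
        m = rebin_macro(c, [19.5, 21.5])
        assert abs(m.contrast[0]) < abs(c.contrast).min()

    def test_counts_conserved(self):
        counts = np.arange(2 * 231).reshape(1, 2, 231)
        r = CountRates(counts, np.arange(20.0, 251.0), 1e6)
        m = rebin_macro(r, [19.5, 80.5, 250.5])
        assert m.counts.sum() == counts.sum()

    def test_overlapping_edges_rejected(self):
        c = ContrastResult(np.array([20.0]), np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            rebin_macro(c, [20.0, 20.0])
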