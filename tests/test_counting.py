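import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcdsim.counting import (CountRecords, analytic_rate, bin_counts,
                             count_np, count_p, count_pixel_events,
                             count_train, sectioned_counts)
from pcdsim.detector import (BiexponentialPulse, CountingConfig,
                             DetectorGeometry, GaussianPulse,
                             RectangularPulse, ResolutionModel)
from pcdsim.pulsetrain import PulseTrain, synthesize
from pcdsim.transport import DepositionEventList

NP_CFG = CountingConfig(behavior="NP", tau_pd_ns=13, tau_np_ns=24)
P_CFG = CountingConfig(behavior="P", tau_pd_ns=13, tau_np_ns=None)


def train_from(times, energies, shape=GaussianPulse(14.0), duration=2000.0):
    n = len(times)
    geom = DetectorGeometry(pitch_um=500.0, shape=(5, 5), thickness_mm=2.0)
    ev = DepositionEventList(
        np.full(n, 2), np.full(n, 2), np.asarray(energies, float),
        np.asarray(times, float), np.arange(n), np.zeros(n, int),
        duration, geom)
    return synthesize(ev, shape, ResolutionModel(0.0), duration, blur=False)


class TestBasicCounting:
    def test_empty_train(self):
        train = train_from([], [])
        assert len(count_np(train, NP_CFG)) == 0
        assert len(count_p(train, P_CFG)) == 0

    def test_isolated_pulse_exactly_one_count(self):
        # the defining guarantee: one count for the highest-energy photon
        # when there is no pile-up
        train = train_from([500.0], [120.0])
        for cfg, counter in [(NP_CFG, count_np), (P_CFG, count_p)]:
            rec = counter(train, cfg)
            assert len(rec) == 1
            assert rec.energy_keV[0] == pytest.approx(120.0, rel=1e-9)

    def test_two_close_pulses_pile_up_to_one_count(self):
        # two 60 keV pulses 5 ns apart: one count at the summed-peak energy
        train = train_from([500.0, 505.0], [60.0, 60.0])
        rec = count_np(train, NP_CFG)
        assert len(rec) == 1
        sig = train.signals[2, 2]
        assert rec.energy_keV[0] == pytest.approx(sig.max(), rel=1e-12)
        assert rec.energy_keV[0] > 60.0

    def test_sustained_plateau_single_p_count(self):
        # a plateau above threshold for 10 tau_pd yields exactly one P count
        geom_shape = (5, 5)
        sig = np.zeros((5, 5, 500))
        sig[2, 2, 100:100 + 10 * P_CFG.tau_pd_ns] = 50.0
        train = PulseTrain(sig, 500.0, 0)
        rec = count_p(train, P_CFG)
        assert len(rec) == 1

    def test_np_requires_fresh_crossing_after_window(self):
        # signal stays above threshold past the window end: no second count
        sig = np.zeros((5, 5, 500))
        sig[2, 2, 100:180] = 50.0  # 80 ns > tau_np = 24
        train = PulseTrain(sig, 500.0, 0)
        assert len(count_np(train, NP_CFG)) == 1
        # after it falls below, a new crossing may trigger again
        sig2 = sig.copy()
        sig2[2, 2, 200:210] = 50.0
        assert len(count_np(PulseTrain(sig2, 500.0, 0), NP_CFG)) == 2

    def test_registered_energy_at_least_threshold(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1500, 60))
        e = rng.uniform(10, 130, 60)
        train = train_from(t, e)
        for cfg, counter in [(NP_CFG, count_np), (P_CFG, count_p)]:
            rec = counter(train, cfg)
            assert np.all(rec.energy_keV >= cfg.threshold_keV)


class TestBinning:
    def records(self, energies):
        n = len(energies)
        return CountRecords(np.full(n, 2), np.full(n, 2),
                            np.arange(n, dtype=float),
                            np.asarray(energies, float))

    def test_bin_assignment(self):
        r = bin_counts(self.records([20.2]), NP_CFG, 1e6, (5, 5))
        assert r.counts[2, 2, 0] == 1  # bin centered at 20 keV

    def test_out_of_range_discarded(self):
        r = bin_counts(self.records([300.0, 10.0, 250.4, 19.4]),
                       NP_CFG, 1e6, (5, 5))
        assert r.counts.sum() == 1  # only 250.4 lands in the last bin

    def test_discard_only(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(0, 400, 500)
        r = bin_counts(self.records(e), NP_CFG, 1e6, (5, 5))
        assert r.counts.sum() <= 500

    def test_rates(self):
        r = bin_counts(self.records([60.0] * 10), NP_CFG, 1e6, (5, 5))
        assert r.rates[2, 2, 40] == pytest.approx(10 / 1e-3)


class TestSectioned:
    def test_section_stationarity(self):
        rng = np.random.default_rng(2)
        n = 2000
        t = np.sort(rng.uniform(0, 1e6, n))
        rec = CountRecords(np.full(n, 2), np.full(n, 2), t, np.full(n, 60.0))
        s = sectioned_counts(rec, NP_CFG, 1e6, 1e4, (5, 5))
        per_sec = s.counts[:, 2, 2, :].sum(axis=1)
        assert s.n_sections == 100
        assert per_sec.sum() == n
        mean = per_sec.mean()
        assert np.all(np.abs(per_sec - mean) < 6 * np.sqrt(mean))

    def test_poisson_variance_ratio(self):
        rng = np.random.default_rng(3)
        lam = 20.0
        counts = rng.poisson(lam, 1000)
        t = np.concatenate([np.sort(rng.uniform(i * 1e3, (i + 1) * 1e3, c))
                            for i, c in enumerate(counts)])
        n = t.size
        rec = CountRecords(np.full(n, 2), np.full(n, 2), t, np.full(n, 60.0))
        s = sectioned_counts(rec, NP_CFG, 1e6, 1e3, (5, 5))
        per_sec = s.counts[:, 2, 2, :].sum(axis=1)
        ratio = per_sec.var(ddof=1) / per_sec.mean()
        # variance/mean ~ 1 for Poisson; 3 sigma of the ratio ~ 3*sqrt(2/S)
        assert abs(ratio - 1.0) < 3 * np.sqrt(2.0 / 1000)

    def test_single_section_rejected(self):
        rec = CountRecords(np.array([2]), np.array([2]),
                           np.array([1.0]), np.array([60.0]))
        with pytest.raises(ValueError):
            sectioned_counts(rec, NP_CFG, 1e6, 1e6, (5, 5))


class TestAnalyticRate:
    def test_closed_forms(self):
        assert analytic_rate("NP", 1e6, 100e-9) == pytest.approx(1e6 / 1.1)
        assert analytic_rate("P", 1e6, 100e-9) == pytest.approx(
            1e6 * np.exp(-0.1))

    def test_zero_dead_time(self):
        assert analytic_rate("NP", 1e6, 0.0) == 1e6
        assert analytic_rate("P", 1e6, 0.0) == 1e6

    def test_validation(self):
        with pytest.raises(ValueError):
            analytic_rate("NP", 1e6, -1e-9)
        with pytest.raises(ValueError):
            analytic_rate("weird", 1e6, 0.0)


class TestFastPathEquivalence:
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.sampled_from(["NP", "P"]),
           st.sampled_from([3e-4, 3e-3, 2e-2]))
    @settings(max_examples=12, deadline=None)
    def test_event_counting_matches_dense_train(self, seed, behavior, rate):
        """The clustered/dense event-based counter is exactly equivalent
        to synthesizing the full train and scanning it."""
        rng = np.random.default_rng(seed)
        shape = BiexponentialPulse(16.0, 7.0)
        cfg = CountingConfig(behavior=behavior, tau_pd_ns=11,
                             tau_np_ns=51 if behavior == "NP" else None)
        T = 5e4
        n = rng.poisson(rate * T)
        t = np.sort(rng.uniform(0, T - 400, n))
        e = rng.uniform(5, 140, n)
        train = train_from(t, e, shape=shape, duration=T)
        rec = count_train(train, cfg)
        tt, ee = count_pixel_events(t, e, shape.kernel(), cfg)
        assert tt.size == len(rec)
        assert np.allclose(np.sort(tt), np.sort(rec.time_ns))
        assert np.allclose(np.sort(ee), np.sort(rec.energy_keV))


class TestDeadTimeOracles:
    def _mono_rate(self, behavior, kernel, cfg, n_per_ns, T, seed):
        rng = np.random.default_rng(seed)
        n = rng.poisson(n_per_ns * T)
        t = np.sort(rng.uniform(0, T, n))
        tt, _ = count_pixel_events(t, np.full(n, 60.0), kernel, cfg)
        return tt.size

    @pytest.mark.parametrize("ntau", [0.01, 0.1, 1.0])
    def test_np_matches_nonparalyzable_formula(self, ntau):
        # narrow rectangular pulses: the analysis window is the dead time
        tau = 100e-9
        cfg = CountingConfig(behavior="NP", tau_pd_ns=2, tau_np_ns=100)
        kernel = RectangularPulse(2.0).kernel()
        n_rate = ntau / tau
        expect = analytic_rate("NP", n_rate, tau)
        T = max(3e5, 15000 / (expect * 1e-9))
        got = self._mono_rate("NP", kernel, cfg, n_rate * 1e-9, T, 11)
        exp_counts = expect * T * 1e-9
        assert abs(got - exp_counts) < 3 * np.sqrt(exp_counts)

    @pytest.mark.parametrize("ntau", [0.01, 0.1, 1.0])
    def test_p_matches_paralyzable_formula(self, ntau):
        # rectangle width = time over threshold = the paralyzable dead time
        w = 50
        tau = w * 1e-9
        cfg = CountingConfig(behavior="P", tau_pd_ns=10, tau_np_ns=None)
        kernel = RectangularPulse(float(w)).kernel()
        n_rate = ntau / tau
        expect = analytic_rate("P", n_rate, tau)
        T = max(3e5, 15000 / (expect * 1e-9))
        got = self._mono_rate("P", kernel, cfg, n_rate * 1e-9, T, 13)
        exp_counts = expect * T * 1e-9
        # small ns-discretization bias at high n tau; 3 sigma + 1.5%
        assert abs(got - exp_counts) < 3 * np.sqrt(exp_counts) + 0.015 * exp_counts

    def test_low_rate_p_equals_np(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 1e6, 50))
        e = np.full(50, 90.0)
        shape = GaussianPulse(14.0)
        np_t, _ = count_pixel_events(t, e, shape.kernel(), NP_CFG)
        p_t, _ = count_pixel_events(t, e, shape.kernel(), P_CFG)
        assert np.array_equal(np_t, p_t)

    def test_np_count_bound(self):
        # NP counts cannot exceed floor(T / tau_np) + 1
        rng = np.random.default_rng(6)
        T = 5e4
        t = np.sort(rng.uniform(0, T, 20000))
        e = np.full(t.size, 120.0)
        tt, _ = count_pixel_events(t, e, GaussianPulse(14.0).kernel(), NP_CFG)
        assert tt.size <= T // NP_CFG.tau_np_ns + 1

    def test_np_rate_monotone_p_rate_peaks(self):
        """The NP output rate saturates monotonically over the moderate
        pile-up decades while the P output rate reaches a maximum.  (At
        extreme rates where the summed signal never falls below threshold,
        the fresh-crossing retrigger rule starves both counters; the NP
        monotonicity therefore covers the decades below that regime.)"""
        shape = GaussianPulse(14.0)
        np_rates, p_rates = [], []
        for i, lam in enumerate([1e-4, 1e-3, 1e-2, 1e-1, 4e-1]):
            rng = np.random.default_rng(100 + i)
            T = 4e5
            n = rng.poisson(lam * T)
            t = np.sort(rng.uniform(0, T, n))
            e = np.full(n, 60.0)
            a, _ = count_pixel_events(t, e, shape.kernel(), NP_CFG)
            b, _ = count_pixel_events(t, e, shape.kernel(), P_CFG)
            np_rates.append(a.size)
            p_rates.append(b.size)
        assert np.all(np.diff(np_rates[:4]) >= 0)
        assert np.all(np.asarray(np_rates) <= np.asarray(p_rates))
        assert np.argmax(p_rates) < len(p_rates) - 1
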