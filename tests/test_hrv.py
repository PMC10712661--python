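import numpy as np
import pytest
from scipy import integrate
from scipy import stats as spstats

from emophys import hrv
from emophys.dsp import SignalTrace
from emophys.synthetic import RRGroundTruth, BVPGroundTruth, simulate_ecg_bvp, simulate_rr_ig


@pytest.fixture(scope="module")
def stationary_rr():
    truth = RRGroundTruth(theta0=0.8, shape=50.0)
    rr, _ = simulate_rr_ig(900.0, truth, seed=7)
    return rr


class TestPreprocessECG:
    def test_rate_contract(self):
        tr = SignalTrace(np.zeros(20480), 2048.0)  # 10 s
        out = hrv.preprocess_ecg(tr)
        assert out.rate == 250.0
        assert out.n_samples == 2500

    def test_constant_preserved(self):
        out = hrv.preprocess_ecg(SignalTrace(np.full(20480, 1.5), 2048.0))
        assert np.allclose(out.data, 1.5, atol=1e-9)

    def test_stopband(self):
        t = np.arange(20480) / 2048.0
        tr = SignalTrace(np.sin(2 * np.pi * 200.0 * t), 2048.0)
        out = hrv.preprocess_ecg(tr)
        assert np.std(out.data[200:-200]) < 0.07


class TestDetectRPeaks:
    def test_regular_spike_train(self):
        rr_true = hrv.RRSeries(np.arange(1.0, 59.0, 0.8))
        ecg, _ = simulate_ecg_bvp(rr_true, BVPGroundTruth(), rate=2048.0,
                                  duration=60.0)
        det = hrv.detect_rpeaks(hrv.preprocess_ecg(ecg))
        assert len(det) == len(rr_true)
        assert np.all(np.abs(det.intervals - 0.8) < 0.004)

    def test_pqrst_template(self):
        rr_true = hrv.RRSeries(np.arange(1.0, 59.0, 0.85))
        ecg, _ = simulate_ecg_bvp(rr_true, BVPGroundTruth(), rate=2048.0,
                                  duration=60.0, template="pqrst")
        det = hrv.detect_rpeaks(hrv.preprocess_ecg(ecg))
        assert abs(len(det) - len(rr_true)) <= 1
        assert np.median(np.abs(det.intervals - 0.85)) < 0.004

    def test_flat_signal_empty(self):
        with pytest.warns(UserWarning):
            det = hrv.detect_rpeaks(SignalTrace(np.zeros(2500), 250.0))
        assert len(det) == 0

    def test_missed_beat_gap_flagged_by_guard(self):
        times = np.delete(np.arange(1.0, 30.0, 0.8), [10, 11, 12])
        rr = hrv.RRSeries(times)  # 3.2 s gap where beats were dropped
        mask = rr.physiologic_mask()
        assert mask.sum() == len(rr.intervals) - 1  # exactly one flagged

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv.detect_rpeaks(SignalTrace(np.zeros(250), 250.0))


class TestIGDensity:
    @pytest.mark.parametrize("seed", range(4))
    def test_normalization_and_mean_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            mu = rng.uniform(0.4, 1.5)
            shape = rng.uniform(5.0, 500.0)
            # split at the mode so quad resolves the narrow peak
            total = sum(integrate.quad(hrv.ig_density, a, b, args=(mu, shape))[0]
                        for a, b in ((1e-9, mu), (mu, 50.0)))
            mean = sum(integrate.quad(
                lambda w: w * hrv.ig_density(w, mu, shape), a, b)[0]
                for a, b in ((1e-9, mu), (mu, 50.0)))
            assert total == pytest.approx(1.0, abs=1e-6)
            assert mean == pytest.approx(mu, abs=1e-6)

    def test_matches_scipy(self):
        w = np.linspace(0.1, 3.0, 50)
        mu, lam = 0.8, 40.0
        ours = hrv.ig_density(w, mu, lam)
        ref = spstats.invgauss.pdf(w, mu / lam, scale=lam)
        assert np.allclose(ours, ref, rtol=1e-12)

    def test_small_w_limit(self):
        assert hrv.ig_density(1e-6, 0.8, 50.0) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hrv.ig_density(-1.0, 0.8, 50.0)
        with pytest.raises(ValueError):
            hrv.ig_density(0.5, -0.8, 50.0)

    def test_variance_closed_form(self):
        assert hrv.ig_variance(0.8, 50.0) == 0.8 ** 3 / 50.0


class TestMuRR:
    def test_order0(self):
        p = hrv.IGParams(theta0=0.8, ar_coeffs=np.array([]), shape=50.0, order=0)
        assert hrv.mu_rr(p, np.array([])) == 0.8

    def test_forced_arithmetic(self):
        p = hrv.IGParams(theta0=0.1, ar_coeffs=np.array([0.5]), shape=50.0, order=1)
        assert hrv.mu_rr(p, np.array([0.8])) == pytest.approx(0.5)

    def test_stationary_closed_form(self):
        p = hrv.IGParams(theta0=0.2, ar_coeffs=np.array([0.3, 0.2, 0.1]),
                         shape=50.0, order=3)
        r = 0.9
        assert hrv.mu_rr(p, np.full(3, r)) == pytest.approx(0.2 + 0.6 * r)

    def test_wrong_history_length(self):
        p = hrv.IGParams(theta0=0.1, ar_coeffs=np.array([0.5]), shape=50.0, order=1)
        with pytest.raises(ValueError):
            hrv.mu_rr(p, np.array([0.8, 0.7]))


class TestLocalMLFit:
    def test_order0_recovery(self, stationary_rr):
        p = hrv.local_ml_fit(stationary_rr, stationary_rr.r_times[-1],
                             order=0, window_s=1e9, forgetting=1.0)
        assert p.theta0 == pytest.approx(0.8, rel=0.02)
        assert p.shape == pytest.approx(50.0, rel=0.15)

    def test_ar2_recovery(self):
        truth = RRGroundTruth(theta0=0.3, ar_coeffs=(0.4, 0.2), shape=1200.0)
        rr, _ = simulate_rr_ig(900.0, truth, seed=2)
        assert len(rr) >= 1000
        p = hrv.local_ml_fit(rr, rr.r_times[-1], order=2, window_s=1e9,
                             forgetting=1.0)
        rmse = np.sqrt(np.mean((p.ar_coeffs - np.array([0.4, 0.2])) ** 2))
        assert rmse < 0.1

    def test_constant_intervals_degenerate(self):
        rr = hrv.RRSeries(np.arange(0.0, 100.0, 0.8)
                          + np.random.default_rng(0).normal(0, 1e-5, 125))
        p = hrv.local_ml_fit(rr, 100.0, order=0, window_s=1e9, forgetting=1.0)
        assert p.theta0 == pytest.approx(0.8, abs=1e-3)
        assert hrv.ig_variance(p.theta0, p.shape) < 1e-6

    def test_insufficient_beats_returns_none(self, stationary_rr):
        assert hrv.local_ml_fit(stationary_rr, 2.0, order=8, window_s=5.0) is None

    def test_bad_forgetting(self, stationary_rr):
        with pytest.raises(ValueError):
            hrv.local_ml_fit(stationary_rr, 100.0, forgetting=1.5)

    def test_ml_property_fitted_beats_generator(self):
        # fitted likelihood >= generator likelihood in >= 95% of fits
        wins = 0
        for seed in range(20):
            truth = RRGroundTruth(theta0=0.8, shape=100.0)
            rr, _ = simulate_rr_ig(120.0, truth, seed=seed)
            fit = hrv.local_ml_fit(rr, rr.r_times[-1], order=0, window_s=1e9,
                                   forgetting=1.0)
            gen = hrv.IGParams(theta0=0.8, ar_coeffs=np.array([]), shape=100.0,
                               order=0)
            if hrv.log_likelihood(fit, rr) >= hrv.log_likelihood(gen, rr):
                wins += 1
        assert wins >= 19


class TestSpectrum:
    def test_flat_spectrum_lfn(self):
        p = hrv.IGParams(theta0=0.8, ar_coeffs=np.array([]), shape=50.0, order=0)
        _, bands = hrv.instantaneous_spectrum(p, 0.8)
        expected = (0.15 - 0.04) / (0.5 - 0.04)
        assert bands["lfn"] == pytest.approx(expected, abs=0.005)

    def test_resonant_ar2_hf_dominates(self):
        # AR(2) pole pair at 0.25 Hz (sampling interval 0.8 s)
        dt, f0, r = 0.8, 0.25, 0.9
        phi1 = 2 * r * np.cos(2 * np.pi * f0 * dt)
        phi2 = -r ** 2
        p = hrv.IGParams(theta0=0.1, ar_coeffs=np.array([phi1, phi2]),
                         shape=50.0, order=2)
        _, bands = hrv.instantaneous_spectrum(p, 0.8)
        assert bands["hf"] > bands["lf"]

    def test_normalization_identity(self):
        p = hrv.IGParams(theta0=0.8, ar_coeffs=np.array([0.2, -0.1]),
                         shape=50.0, order=2)
        _, bands = hrv.instantaneous_spectrum(p, 0.8)
        assert bands["lfn"] + bands["hfn"] == pytest.approx(1.0)
        for k in ("vlf", "lf", "hf", "tot"):
            assert bands[k] >= 0


class TestTrack:
    def test_stationary_mu_recovery(self, stationary_rr):
        tk = hrv.track(stationary_rr, grid_step=2.0, order=4, window_s=90.0)
        mus = [e.mu_rr for e in tk]
        assert np.mean(mus) == pytest.approx(0.8, rel=0.02)
        for e in tk:
            assert e.lfn + e.hfn == pytest.approx(1.0)
            assert min(e.vlf, e.lf, e.hf, e.tot) >= 0

    def test_lf_modulated_lf_hf(self):
        truth = RRGroundTruth(theta0=0.8, shape=2000.0,
                              mean_modulation=[(0.1, 0.05)])
        rr, _ = simulate_rr_ig(240.0, truth, seed=3)
        tk = hrv.track(rr, grid_step=2.0, order=8, window_s=90.0)
        assert np.nanmean([e.lf_hf for e in tk]) > 1.0

    def test_empty_series(self):
        assert hrv.track(hrv.RRSeries(np.array([]))) == []

    def test_sigma2_positive_and_plausible(self, stationary_rr):
        # generator variance mu^3/lambda = 0.8^3/50
        expected = 0.8 ** 3 / 50.0
        tk = hrv.track(stationary_rr, grid_step=10.0, order=2, window_s=90.0)
        s2 = np.array([e.sigma2 for e in tk])
        assert np.all(s2 > 0)
        assert np.median(s2) == pytest.approx(expected, rel=0.5)


class TestHRVFeatures:
    def test_single_point(self):
        e = hrv.InstantaneousEstimate(t=5.0, mu_rr=0.8, sigma2=0.01, vlf=1.0,
                                      lf=2.0, hf=1.0, tot=4.0, lf_hf=2.0,
                                      lfn=2 / 3, hfn=1 / 3)
        f = hrv.hrv_features([e], (0.0, 10.0))
        assert f.mu_rr == 0.8
        assert f.lf_hf == 2.0

    def test_window_outside_track(self):
        e = hrv.InstantaneousEstimate(t=5.0, mu_rr=0.8, sigma2=0.01, vlf=1.0,
                                      lf=2.0, hf=1.0, tot=4.0, lf_hf=2.0,
                                      lfn=2 / 3, hfn=1 / 3)
        f = hrv.hrv_features([e], (100.0, 200.0))
        assert all(np.isnan(v) for v in f.as_dict().values())


class TestTimeRescaling:
    def test_uniform_on_well_specified_data(self, stationary_rr):
        p = hrv.local_ml_fit(stationary_rr, stationary_rr.r_times[-1],
                             order=0, window_s=1e9, forgetting=1.0)
        _, pval = hrv.time_rescaling_ks(p, stationary_rr)
        assert pval > 0.01
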