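import numpy as np
import pytest

from emophys import protocol as proto
from emophys import synthetic as syn
from emophys.dsp import band_power, downsample, welch_psd, SignalTrace


class TestRRSimulation:
    def test_degenerate_variance(self):
        truth = syn.RRGroundTruth(theta0=0.8, shape=1e7)
        rr, _ = syn.simulate_rr_ig(200.0, truth, seed=0)
        cv = np.std(rr.intervals) / np.mean(rr.intervals)
        assert cv < 0.01
        assert np.allclose(rr.intervals, 0.8, atol=0.01)

    def test_mean_recovery_monte_carlo(self):
        truth = syn.RRGroundTruth(theta0=0.8, shape=50.0)
        rr, _ = syn.simulate_rr_ig(8000.0, truth, seed=1)
        n = len(rr.intervals)
        assert n >= 9000
        sd = np.sqrt(0.8 ** 3 / 50.0)  # analytic inverse-Gaussian SD
        se = sd / np.sqrt(n)
        assert abs(np.mean(rr.intervals) - 0.8) < 3 * se

    def test_modulation_peak_in_lf_band(self):
        truth = syn.RRGroundTruth(theta0=0.8, shape=5000.0,
                                  mean_modulation=[(0.1, 0.05)])
        rr, _ = syn.simulate_rr_ig(600.0, truth, seed=2)
        # spectral oracle: resample RR intervals to 4 Hz, Welch PSD
        t_grid = np.arange(rr.r_times[1], rr.r_times[-1], 0.25)
        rr_interp = np.interp(t_grid, rr.r_times[1:], rr.intervals)
        spec = welch_psd(SignalTrace(rr_interp, 4.0), segment_len=1024)
        mask = spec.frequencies > 0.01
        peak_f = spec.frequencies[mask][np.argmax(spec.density[mask])]
        assert 0.04 <= peak_f <= 0.15

    def test_unstable_ar_rejected(self):
        with pytest.raises(ValueError):
            syn.RRGroundTruth(theta0=0.1, ar_coeffs=(1.2,))

    def test_strictly_increasing(self):
        truth = syn.RRGroundTruth(theta0=0.7, ar_coeffs=(0.1,), shape=100.0)
        rr, _ = syn.simulate_rr_ig(120.0, truth, seed=3)
        assert np.all(np.diff(rr.r_times) > 0)

    def test_determinism(self):
        truth = syn.RRGroundTruth()
        a, _ = syn.simulate_rr_ig(60.0, truth, seed=9)
        b, _ = syn.simulate_rr_ig(60.0, truth, seed=9)
        assert np.array_equal(a.r_times, b.r_times)


class TestGSRSimulation:
    def test_tonic_only_flat_phasic(self):
        from emophys import gsr
        truth = syn.SCRGroundTruth()
        tr = syn.simulate_gsr(truth, 60.0, 256.0, seed=0, noise_sd=0.0)
        d = gsr.extract_phasic(gsr.preprocess_gsr(tr))
        assert np.max(np.abs(d.phasic.data)) < 1e-6

    def test_events_outside_duration_rejected(self):
        truth = syn.SCRGroundTruth(event_times=np.array([100.0]),
                                   amplitudes=np.array([0.5]))
        with pytest.raises(ValueError):
            syn.simulate_gsr(truth, 60.0, 256.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_gsr(syn.SCRGroundTruth(), 60.0, 5.0)

    def test_kernel_peaks_at_amplitude(self):
        u = np.linspace(0, 20, 20000)
        k = syn.scr_kernel(u, 0.3, 1.0)
        assert np.max(k) == pytest.approx(1.0, abs=1e-4)

    def test_invalid_taus(self):
        with pytest.raises(ValueError):
            syn.SCRGroundTruth(rise_tau=2.0, decay_tau=1.0)


class TestECGBVPSimulation:
    def test_empty_rr_gives_empty_traces(self):
        from emophys.hrv import RRSeries
        ecg, bvp = syn.simulate_ecg_bvp(RRSeries(np.array([])),
                                        syn.BVPGroundTruth(), rate=256.0,
                                        duration=2.0)
        assert ecg.n_samples == 512
        assert np.allclose(ecg.data, 0.0) and np.allclose(bvp.data, 0.0)

    def test_one_spike_per_beat(self):
        from emophys.hrv import RRSeries
        from scipy.signal import find_peaks
        rr = RRSeries(np.arange(1.0, 10.0, 0.8))
        ecg, _ = syn.simulate_ecg_bvp(rr, syn.BVPGroundTruth(), rate=512.0,
                                      duration=11.0)
        pk, _ = find_peaks(ecg.data, height=0.5)
        assert len(pk) == len(rr)

    def test_pat_exceeding_rr_rejected(self):
        from emophys.hrv import RRSeries
        rr = RRSeries(np.arange(0.0, 5.0, 0.4))
        with pytest.raises(ValueError):
            syn.simulate_ecg_bvp(rr, syn.BVPGroundTruth(pat=0.5))


class TestEEGSimulation:
    def test_zero_powers_flat(self):
        tr = syn.simulate_eeg(syn.EEGGroundTruth.uniform(0.0), 10.0, 300.0, seed=0)
        assert np.allclose(tr.data, 0.0)

    def test_band_power_targets_met(self):
        truth = syn.EEGGroundTruth.uniform(2.0)
        tr = syn.simulate_eeg(truth, 60.0, 300.0, seed=1)
        spec = welch_psd(SignalTrace(tr.channel("Fz"), 300.0), segment_len=600)
        assert band_power(spec, 8.0, 12.0) == pytest.approx(2.0, rel=0.25)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            syn.EEGGroundTruth({("frontal", "beta"): -1.0})


class TestPupilSimulation:
    def test_trivial_constant(self):
        truth = syn.PupilGroundTruth(baseline=5.0)
        left, right = syn.simulate_pupil(truth, 30.0, 60.0, seed=0, noise_sd=0.0)
        assert np.allclose(left.data, 5.0)
        assert np.allclose(right.data, 5.0)

    def test_blinks_out_of_range(self):
        truth = syn.PupilGroundTruth(blink_intervals_left=[(5.0, 5.5)])
        left, _ = syn.simulate_pupil(truth, 10.0, 60.0, seed=0)
        t = left.times()
        sel = (t >= 5.0) & (t < 5.5)
        assert np.all((left.data[sel] < 2.0) | (left.data[sel] > 8.0))

    def test_baseline_range_enforced(self):
        with pytest.raises(ValueError):
            syn.PupilGroundTruth(baseline=1.0)


class TestExperiment:
    def test_determinism(self, small_protocol_config):
        sched = proto.build_schedule(small_protocol_config)
        a = syn.simulate_experiment(sched, syn.null_effect_map(), seed=5,
                                    signals=("gsr",))
        b = syn.simulate_experiment(sched, syn.null_effect_map(), seed=5,
                                    signals=("gsr",))
        assert np.array_equal(a.gsr.data, b.gsr.data)

    def test_traces_cover_schedule(self, small_protocol_config):
        sched = proto.build_schedule(small_protocol_config)
        rec = syn.simulate_experiment(sched, syn.null_effect_map(), seed=6,
                                      signals=("gsr", "pupil"))
        assert rec.gsr.duration >= sched.t_end
        assert rec.pupil_left.duration >= sched.t_end

    def test_effect_recorded_in_truth(self, small_protocol_config):
        sched = proto.build_schedule(small_protocol_config)
        em = syn.EffectMap(overrides={
            ("IADS", "arousal"): syn.SessionEffect(scr_amp_us=1.5)})
        rec = syn.simulate_experiment(sched, em, seed=7, signals=("gsr",))
        effects = rec.truth["session_effects"]
        iads_arousal = [v for k, v in effects.items()
                        if k[0] == "IADS" and k[1] == "arousal"]
        assert all(e.scr_amp_us == 1.5 for e in iads_arousal)
        other = [v for k, v in effects.items() if k[0] != "IADS"]
        assert all(e.scr_amp_us == 0.5 for e in other)

    def test_full_multimodal_small(self, small_protocol_config):
        sched = proto.build_schedule(small_protocol_config)
        rec = syn.simulate_experiment(sched, syn.null_effect_map(), seed=8)
        assert rec.ecg is not None and rec.eeg is not None
        assert rec.eeg.n_channels == 21
        assert rec.rr_true is not None and len(rec.rr_true) > 100
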