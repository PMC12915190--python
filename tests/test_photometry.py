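import numpy as np
import pytest

from photomics.errors import (
    DataError,
    DegenerateFitError,
    EmptyResultError,
    ParameterError,
)
from photomics.photometry import (
    BoutAnnotation,
    ControlFit,
    CorrectedTrace,
    EventDetectionParams,
    PhotometryRecording,
    TransientEvent,
    compute_dff,
    detect_events,
    extract_peri_event,
    fit_control_channel,
    fit_decay_tau,
    mean_peri_event_z,
    segment_auc,
    summarize_events,
    zscore_trace,
)
from photomics.synthgen import (
    GroundTruthEvents,
    PhotometrySimParams,
    simulate_photometry,
    transient_waveform,
)

from conftest import make_trace

FS = 20.0


def rec_from(signal, control, fs=FS):
    t = np.arange(len(signal)) / fs
    return PhotometryRecording(time=t, f_signal=signal, f_control=control,
                               sampling_rate=fs)


class TestControlFit:
    def test_identity_channels(self, flat_recording):
        fit = fit_control_channel(flat_recording)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.slope == pytest.approx(1.0)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.fitted, flat_recording.f_signal)

    def test_affine_relation_recovered(self):
        # f_signal = 2*f_control + 1 exactly -> (a, b) = (1, 2); the normal
        # equations have this as their unique zero-residual solution
        control = 100.0 + np.sin(np.arange(200) / 10.0)
        fit = fit_control_channel(rec_from(2 * control + 1, control))
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)

    def test_constant_control_raises(self):
        sig = 100.0 + np.arange(50.0)
        with pytest.raises(DegenerateFitError):
            fit_control_channel(rec_from(sig, np.full(50, 7.0)))

    def test_nan_raises(self):
        sig = np.linspace(99, 101, 50)
        ctrl = sig.copy()
        ctrl[3] = np.nan
        with pytest.raises(DataError):
            fit_control_channel(rec_from(sig, ctrl))


class TestComputeDff:
    def test_printed_formula(self):
        # one sample with f_signal 110 over fitted 100 -> dff = 0.10
        sig = np.array([100.0, 110.0, 100.0])
        ctrl = np.array([100.0, 100.1, 100.2])
        rec = rec_from(sig, ctrl)
        fit = ControlFit(0.0, 1.0, np.full(3, 100.0), 0.0)
        trace = compute_dff(rec, fit)
        assert trace.dff[1] == pytest.approx(0.10)

    def test_perfect_fit_gives_zero(self):
        control = 100.0 + np.cos(np.arange(500) / 30.0)
        rec = rec_from(3 * control + 2, control)
        trace = compute_dff(rec, fit_control_channel(rec))
        assert np.max(np.abs(trace.dff)) < 1e-10

    def test_nonpositive_fitted_raises_with_indices(self):
        rec = rec_from(np.ones(10) * 100, np.linspace(99, 101, 10))
        fitted = np.full(10, 100.0)
        fitted[4] = -1.0
        with pytest.raises(DataError, match="4"):
            compute_dff(rec, ControlFit(0.0, 1.0, fitted, 0.0))

    def test_correlation_with_ground_truth(self):
        params = PhotometrySimParams(
            duration=120.0, event_rate=0.0, artifact_sd=0.05,
            noise_sd=0.05, seed=12,
        )
        truth = GroundTruthEvents(
            [10.0, 35.0, 60.0, 85.0, 110.0], [0.08] * 5, 1.0
        )
        rec, truth = simulate_photometry(params, events=truth)
        trace = compute_dff(rec, fit_control_channel(rec))
        target = transient_waveform(rec.time, truth, params.rise_time)
        r = np.corrcoef(trace.dff, target)[0, 1]
        assert r > 0.95


class TestZScore:
    def test_hand_computed_values(self):
        z = zscore_trace(make_trace([1.0, 2.0, 3.0]))
        # population SD of [1,2,3] is sqrt(2/3)
        np.testing.assert_allclose(
            z.z, [-1.2247448713915890, 0.0, 1.2247448713915890]
        )
        assert z.mean_used == pytest.approx(2.0)
        assert z.sd_used == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        z = zscore_trace(make_trace(rng.normal(3.0, 2.0, 1000)))
        assert abs(np.mean(z.z)) < 1e-10
        assert abs(np.std(z.z) - 1.0) < 1e-10

    def test_constant_trace_raises(self):
        with pytest.raises(DegenerateFitError):
            zscore_trace(make_trace(np.full(100, 0.3)))


class TestPeriEvent:
    def bouts(self, intervals, duration=60.0):
        return BoutAnnotation(intervals=intervals, session_duration=duration)

    def test_constant_zero_trace(self):
        trace = make_trace(np.zeros(1200))
        bouts = self.bouts([(10.0, 15.0, "struggle"),
                            (30.0, 33.0, "struggle")])
        m = extract_peri_event(trace, bouts, "struggle")
        assert m.values.shape == (2, 161)
        assert np.all(m.values == 0)

    def test_index_arithmetic(self):
        # single bout at t=10 s, 2/6 s window at 20 Hz -> z[160:321], 161 pts
        rng = np.random.default_rng(1)
        z = zscore_trace(make_trace(rng.normal(size=1200)))
        bouts = self.bouts([(10.0, 14.0, "struggle")])
        m = extract_peri_event(z, bouts, "struggle", 2.0, 6.0)
        assert m.values.shape == (1, 161)
        np.testing.assert_array_equal(m.values[0], z.z[160:321])
        assert m.relative_time[0] == pytest.approx(-2.0)
        assert m.relative_time[-1] == pytest.approx(6.0)
        assert m.relative_time[40] == pytest.approx(0.0)

    def test_boundary_bout_dropped(self):
        trace = make_trace(np.zeros(1200))
        bouts = self.bouts([(1.0, 3.0, "struggle"), (20.0, 25.0, "struggle")])
        m = extract_peri_event(trace, bouts, "struggle", 2.0, 6.0)
        assert m.n_trials == 1
        assert m.n_dropped == 1

    def test_no_qualifying_bouts_raises(self):
        trace = make_trace(np.zeros(1200))
        bouts = self.bouts([(1.0, 3.0, "struggle")])
        with pytest.raises(EmptyResultError) as err:
            extract_peri_event(trace, bouts, "struggle")
        assert err.value.n_dropped == 1

    def test_label_filtering(self):
        trace = make_trace(np.zeros(1200))
        bouts = self.bouts([(10.0, 15.0, "immobility"),
                            (30.0, 35.0, "struggle")])
        m = extract_peri_event(trace, bouts, "immobility")
        assert m.n_trials == 1
        assert m.align_times[0] == pytest.approx(10.0)


class TestMeanPeriEventZ:
    def test_all_zero(self):
        trace = make_trace(np.zeros(1200))
        bouts = BoutAnnotation([(10.0, 15.0, "struggle")], 60.0)
        m = extract_peri_event(trace, bouts, "struggle")
        per_trial, grand = mean_peri_event_z(m)
        assert np.all(per_trial == 0) and grand == 0.0

    def test_step_signal(self):
        # z = 2 from onset onward, 0 before -> mean over [0, 6] is 2
        dff = np.zeros(1200)
        dff[200:] = 2.0
        trace = make_trace(dff)
        bouts = BoutAnnotation([(10.0, 20.0, "struggle")], 60.0)
        m = extract_peri_event(trace, bouts, "struggle", 2.0, 6.0)
        _, grand = mean_peri_event_z(m, 0.0, 6.0)
        assert grand == pytest.approx(2.0)

    def test_bad_subwindow(self):
        trace = make_trace(np.zeros(1200))
        bouts = BoutAnnotation([(10.0, 15.0, "struggle")], 60.0)
        m = extract_peri_event(trace, bouts, "struggle")
        with pytest.raises(ParameterError):
            mean_peri_event_z(m, 0.0, 10.0)
        with pytest.raises(ParameterError):
            mean_peri_event_z(m, 3.0, 3.0)


class TestDetectEvents:
    def test_constant_trace_whole_trace_raises(self):
        with pytest.raises(DegenerateFitError):
            detect_events(make_trace(np.zeros(100)))

    def test_constant_trace_iterative_zero_events(self):
        params = EventDetectionParams(baseline_mode="iterative_exclusion")
        assert detect_events(make_trace(np.zeros(100)), params) == []

    def test_recovery_on_clean_simulation(self, clean_sim):
        params, rec, truth = clean_sim
        trace = compute_dff(rec, fit_control_channel(rec))
        events = detect_events(trace)
        assert len(events) == truth.n_events == 3
        for ev, t0 in zip(events, truth.onset_times):
            assert abs(ev.onset_t - t0) < 0.5
            assert ev.peak_amp == pytest.approx(0.05, rel=0.05)
        assert summarize_events(events, rec.duration).frequency == \
            pytest.approx(0.3)

    def test_amplitude_floor_suppresses_small_events(self, clean_sim):
        params, _, _ = clean_sim
        truth = GroundTruthEvents([100.0, 300.0, 500.0], [0.01] * 3, 1.0)
        rec, _ = simulate_photometry(params, events=truth)
        trace = compute_dff(rec, fit_control_channel(rec))
        assert detect_events(trace) == []

    def test_monotonicity_in_k_sd_and_floor(self):
        rng = np.random.default_rng(5)
        dff = rng.normal(0, 0.005, 6000)
        dff += transient_waveform(
            np.arange(6000) / FS,
            GroundTruthEvents([30.0, 90.0, 150.0, 210.0, 270.0],
                              [0.06, 0.04, 0.08, 0.03, 0.05], 1.0),
            0.0,
        )
        trace = make_trace(dff)
        counts_k = [len(detect_events(trace, EventDetectionParams(k_sd=k)))
                    for k in (1.0, 2.0, 3.0, 4.0, 6.0)]
        assert counts_k == sorted(counts_k, reverse=True)
        counts_f = [len(detect_events(
            trace, EventDetectionParams(amplitude_floor=f)))
            for f in (0.0, 0.02, 0.05, 0.07)]
        assert counts_f == sorted(counts_f, reverse=True)

    def test_min_separation_merges(self):
        t = np.arange(6000) / FS
        dff = transient_waveform(
            t, GroundTruthEvents([100.0, 100.6], [0.1, 0.1], 0.2), 0.0
        ) + 1e-6 * np.sin(t)  # avoid zero baseline SD
        trace = make_trace(dff)
        few = detect_events(trace, EventDetectionParams(min_separation=5.0))
        many = detect_events(trace, EventDetectionParams(min_separation=0.0))
        assert len(few) == 1
        assert len(many) == 2


class TestDecayTau:
    def test_exact_recovery(self):
        t = np.arange(0, 10, 1 / FS)
        tau, r2 = fit_decay_tau(5.0 * np.exp(-t / 1.0), FS)
        assert tau == pytest.approx(1.0, abs=1e-4)
        assert r2 == pytest.approx(1.0)

    def test_offset_recovery(self):
        t = np.arange(0, 12, 1 / FS)
        tau, _ = fit_decay_tau(2.0 * np.exp(-t / 2.5) + 0.3, FS)
        assert tau == pytest.approx(2.5, rel=1e-3)

    def test_short_segment_flagged_missing(self):
        assert fit_decay_tau([1.0, 0.8, 0.6], FS) == (None, None)

    def test_noisy_recovery_median(self):
        # 200 events, tau 1.5 s, additive noise at 10% of amplitude
        rng = np.random.default_rng(123)
        t = np.arange(0, 10, 1 / FS)
        taus = []
        for _ in range(200):
            amp = rng.uniform(0.5, 2.0)
            y = amp * np.exp(-t / 1.5) + rng.normal(0, 0.1 * amp, len(t))
            tau, _ = fit_decay_tau(y, FS)
            if tau is not None:
                taus.append(tau)
        assert len(taus) >= 190
        assert abs(np.median(taus) - 1.5) / 1.5 < 0.05

    def test_auc_matches_analytic_integral(self):
        # trapezoid over [0, 10*tau] vs closed form A*tau
        amp, tau = 0.5, 1.3
        t = np.arange(0, 10 * tau, 1 / FS)
        auc = segment_auc(amp * np.exp(-t / tau), 1 / FS)
        assert auc == pytest.approx(amp * tau, rel=0.02)


class TestSummarizeEvents:
    def ev(self, **kw):
        base = dict(onset_t=0.0, peak_t=0.1, end_t=1.0, peak_amp=0.05,
                    auc=0.04, decay_tau=1.0, fit_r2=0.99)
        base.update(kw)
        return TransientEvent(**base)

    def test_frequency_arithmetic(self):
        s = summarize_events([self.ev(), self.ev(), self.ev()], 600.0)
        assert s.frequency == pytest.approx(0.3)
        assert s.n_events == 3

    def test_zero_events(self):
        s = summarize_events([], 600.0)
        assert s.frequency == 0.0
        assert s.mean_auc is None and s.mean_tau is None

    def test_failed_tau_excluded_from_mean(self):
        s = summarize_events(
            [self.ev(decay_tau=2.0), self.ev(decay_tau=None, fit_r2=None)],
            60.0,
        )
        assert s.mean_tau == pytest.approx(2.0)
        assert s.n_events == 2

    def test_bad_duration(self):
        with pytest.raises(ParameterError):
            summarize_events([], 0.0)


class TestRecordingValidation:
    def test_nonuniform_time_rejected(self):
        t = np.array([0.0, 0.05, 0.11, 0.15])
        with pytest.raises(DataError):
            PhotometryRecording(t, np.ones(4), np.ones(4), 20.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            PhotometryRecording(np.arange(4) / 20.0, np.ones(4), np.ones(3),
                                20.0)

    def test_bout_overlap_rejected(self):
        with pytest.raises(DataError):
            BoutAnnotation([(0.0, 5.0, "struggle"), (4.0, 8.0, "immobility")],
                           10.0)
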