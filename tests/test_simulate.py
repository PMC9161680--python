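"""Synthetic LFP generator: schedule structure, background statistics, ground truth."""

import numpy as np
import pytest

from thetaburst import simulate
from thetaburst.io import StimSchedule
from thetaburst.simulate import SimulationConfig, generate_schedule, synthesize_recording


class TestSchedule:
    def test_full_session_counts_and_intervals(self):
        sched = generate_schedule([3, 4, 5, 6, 7, 8], trials_per_freq=60, seed=0)
        assert sched.n_trials == 360
        freqs = sched.trial_freqs
        for f in (3, 4, 5, 6, 7, 8):
            assert (freqs == f).sum() == 60
        assert sorted({e.inter_burst_interval_ms for e in sched.events}) == [
            125, 143, 167, 200, 250, 333,
        ]

    def test_spacing_and_jitter_bounds(self):
        sched = generate_schedule([3, 4, 5, 6, 7, 8], trials_per_freq=60, seed=3)
        gaps = np.diff(sched.onsets) / sched.fs
        assert np.all(np.abs(gaps - 3.0) <= 0.2 + 1e-9)
        assert abs(gaps.mean() - 3.0) < 0.05

    def test_trial_structure_matches_burst_parameters(self):
        sched = generate_schedule([4.0], trials_per_freq=1, seed=0)
        ev = sched.events[0]
        # 5 bursts at 250 ms spacing + 5 pulses at 100 Hz in the last burst
        expected_dur = 4 * 0.250 + 4 / 100.0
        assert ev.offset - ev.onset == pytest.approx(expected_dur * sched.fs + 1, abs=1)

    def test_empty_schedule(self):
        sched = generate_schedule([3, 4], trials_per_freq=0, seed=0)
        assert sched.n_trials == 0

    def test_same_seed_bit_identical(self):
        a = generate_schedule([3, 4, 5], trials_per_freq=5, seed=9)
        b = generate_schedule([3, 4, 5], trials_per_freq=5, seed=9)
        assert a.onsets.tolist() == b.onsets.tolist()
        assert a.trial_freqs.tolist() == b.trial_freqs.tolist()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"freqs": []},
            {"freqs": [0.0]},
            {"freqs": [-3.0]},
            {"freqs": [5.0], "jitter": 3.0},
            {"freqs": [5.0], "spacing": 0.5},  # shorter than trial duration
        ],
    )
    def test_invalid_arguments_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_schedule(trials_per_freq=2, seed=0, **kwargs)


class TestRecording:
    def test_same_seed_bit_identical(self):
        sched = generate_schedule([5.0], trials_per_freq=3, seed=1)
        cfg = SimulationConfig(n_channels=2, response_gain=1.0, seed=5)
        r1, _ = synthesize_recording(cfg, sched)
        r2, _ = synthesize_recording(cfg, sched)
        assert np.array_equal(r1.signal, r2.signal)

    def test_schedule_exceeding_duration_raises(self):
        sched = generate_schedule([5.0], trials_per_freq=10, seed=1)
        cfg = SimulationConfig(n_channels=1, duration_s=5.0)
        with pytest.raises(ValueError, match="beyond"):
            synthesize_recording(cfg, sched)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_background_spectral_slope(self, alpha):
        """Log-log least-squares slope over 1-40 Hz recovers the 1/f exponent."""
        cfg = SimulationConfig(
            n_channels=2, background_exponent=alpha, duration_s=240.0, seed=21
        )
        rec, _ = synthesize_recording(cfg, StimSchedule([], cfg.fs))
        from scipy.signal import welch

        f, p = welch(rec.signal, fs=cfg.fs, nperseg=int(8 * cfg.fs))
        sel = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log(f[sel]), np.log(p[:, sel].mean(axis=0)), 1)[0]
        assert abs(-slope - alpha) < 0.15

    def test_ground_truth_records_injection(self):
        sched = generate_schedule([4.0, 6.0], trials_per_freq=2, seed=2)
        cfg = SimulationConfig(n_channels=3, response_gain=np.array([0.0, 1.0, 2.0]), seed=2)
        _, truth = synthesize_recording(cfg, sched)
        assert truth.trial_freqs.tolist() == sched.trial_freqs.tolist()
        assert set(truth.trial_freqs) <= {4.0, 6.0}
        assert truth.response_gain.tolist() == [0.0, 1.0, 2.0]
        assert truth.decay_tau == cfg.decay_tau

    def test_artifact_strictly_confined_to_stimulation(self):
        """With and without artifact, traces differ only inside [onset, offset)."""
        sched = generate_schedule([5.0], trials_per_freq=3, seed=3)
        base = SimulationConfig(n_channels=2, seed=4)
        with_art = SimulationConfig(
            n_channels=2, artifact_amplitude=50.0, artifact_channels=(1,), seed=4
        )
        r0, _ = synthesize_recording(base, sched)
        r1, _ = synthesize_recording(with_art, sched)
        diff = r1.signal - r0.signal
        assert np.any(diff[1] != 0)
        assert np.all(diff[0] == 0)  # non-artifact channel untouched
        inside = np.zeros(r0.n_samples, dtype=bool)
        for ev in sched.events:
            inside[ev.onset : ev.offset] = True
        assert np.all(diff[1][~inside] == 0)

    def test_evoked_frequency_recovered_by_direct_dft(self):
        """Post-stimulation spectrum of a strong 5 Hz injection peaks at 5 Hz.

        Oracle: rectangular-window periodogram of the raw generated trace.
        """
        sched = generate_schedule([5.0], trials_per_freq=5, seed=6)
        cfg = SimulationConfig(n_channels=1, response_gain=10.0, decay_tau=0.5, seed=6)
        rec, _ = synthesize_recording(cfg, sched)
        fs = rec.fs
        for ev in sched.events:
            seg = rec.signal[0, ev.offset : ev.offset + int(fs)]
            freqs = np.fft.rfftfreq(seg.size, 1 / fs)
            power = np.abs(np.fft.rfft(seg)) ** 2
            band = (freqs >= 3) & (freqs <= 8)
            assert freqs[band][power[band].argmax()] == pytest.approx(5.0, abs=0.5)

    def test_invalid_config_raises(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=1, fs=50.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=1, decay_tau=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=2, response_gain=np.array([1.0, -1.0]))

    def test_no_coupling_coherence_at_estimator_bias_floor(self):
        """With independent channels, estimated coherence matches the no-coupling
        bias floor measured on a matched white-noise Monte-Carlo oracle."""
        from thetaburst.connectivity import baseline_coherence
        from thetaburst.io import ChannelInfo, Recording

        cfg = SimulationConfig(n_channels=2, duration_s=120.0, seed=31)
        rec, _ = synthesize_recording(cfg, StimSchedule([], cfg.fs))
        periods = [(10.0 * i, 10.0 * (i + 1)) for i in range(10)]
        net = baseline_coherence(rec, periods)
        rng = np.random.default_rng(99)
        oracle_vals = []
        for _ in range(5):
            white = Recording(
                rng.standard_normal((2, rec.n_samples)),
                rec.fs,
                [ChannelInfo("a"), ChannelInfo("b")],
            )
            oracle_vals.append(baseline_coherence(white, periods).coherence[0, 1])
        floor = np.mean(oracle_vals)
        assert net.coherence[0, 1] == pytest.approx(floor, abs=0.03)


class TestCoupledCohort:
    def test_correlation_out_of_range_raises(self):
        with pytest.raises(ValueError):
            simulate.coupled_cohort(2, SimulationConfig(n_channels=4), 1.5, seed=0)
        with pytest.raises(ValueError):
            simulate.coupled_cohort(0, SimulationConfig(n_channels=4), 0.5, seed=0)

    def test_identical_seed_identical_cohort(self):
        kw = dict(
            n_sessions=1,
            schedule_kwargs={"trials_per_freq": 1},
            baseline_periods=2,
        )
        a = simulate.coupled_cohort(2, SimulationConfig(n_channels=4), 0.5, seed=8, **kw)
        b = simulate.coupled_cohort(2, SimulationConfig(n_channels=4), 0.5, seed=8, **kw)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.recording.signal, sb.recording.signal)
            assert np.array_equal(sa.coupling_to_site, sb.coupling_to_site)

    def test_stim_channel_flagged_and_silent(self):
        sess = simulate.coupled_cohort(
            1,
            SimulationConfig(n_channels=4),
            0.8,
            seed=3,
            n_sessions=1,
            schedule_kwargs={"trials_per_freq": 1},
            baseline_periods=2,
        )[0]
        assert sess.recording.channels[sess.stim_channel].excluded == "stimulated"
        assert sess.ground_truth.response_gain[sess.stim_channel] == 0.0

    def test_requested_correlation_reflected_in_gains(self):
        sessions = simulate.coupled_cohort(
            6,
            SimulationConfig(n_channels=20),
            0.8,
            seed=17,
            n_sessions=1,
            schedule_kwargs={"trials_per_freq": 0},
            baseline_periods=1,
            baseline_span_s=1.0,
        )
        rs = []
        for s in sessions:
            mask = np.arange(20) != s.stim_channel
            bg_sd = np.sqrt(1.0 + s.coupling_to_site[mask] ** 2)
            snr = s.ground_truth.response_gain[mask] / bg_sd
            rs.append(np.corrcoef(snr, s.coupling_to_site[mask])[0, 1])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.1)
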