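"""Synthetic multichannel LFP with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-channel 1/f^alpha ("pink") background activity;
* between-channel coherence induced by shared latent pink sources mixed
  through a channels x sources gain matrix;
* a stimulation-evoked oscillation at each trial's burst frequency that
  onsets with stimulation (linear ramp over the first burst period), persists
  through the stimulation interval, and decays exponentially after offset
  with time constant ``decay_tau``;
* channel response amplitudes proportional to a configurable per-channel
  ``response_gain`` (coupling to the stimulated site);
* an optional high-frequency biphasic pulse-train artifact confined strictly
  to the stimulation interval of designated channels.

Every injected parameter is recorded in a :class:`GroundTruth` so downstream
stages can be checked by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ChannelInfo, Recording, StimEvent, StimSchedule


def trial_duration_s(
    burst_freq: float, bursts: int = 5, pulses_per_burst: int = 5, pulse_freq: float = 100.0
) -> float:
    """Duration from first to last pulse of one trial, in seconds."""
    ibi_s = round(1000.0 / burst_freq) / 1000.0
    return (bursts - 1) * ibi_s + (pulses_per_burst - 1) / pulse_freq


def generate_schedule(
    freqs: list[float],
    trials_per_freq: int = 60,
    spacing: float = 3.0,
    jitter: float = 0.2,
    pulse_freq: float = 100.0,
    pulses_per_burst: int = 5,
    bursts: int = 5,
    fs: float = 500.0,
    seed: int = 0,
    start_s: float = 2.0,
) -> StimSchedule:
    """Randomly interleaved trial schedule.

    ``trials_per_freq`` trials at each burst frequency, consecutive onsets
    separated by ``spacing`` plus uniform jitter on [-jitter, +jitter]. The
    inter-burst interval of a trial at f Hz is round(1000/f) ms, reproducing
    the canonical set {333, 250, 200, 167, 143, 125} ms for 3..8 Hz.
    """
    freqs = [float(f) for f in freqs]
    if not freqs:
        raise ValueError("freqs must be non-empty")
    if any(f <= 0 for f in freqs):
        raise ValueError("burst frequencies must be positive")
    if jitter >= spacing:
        raise ValueError("jitter must be smaller than spacing")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    longest = max(
        trial_duration_s(f, bursts, pulses_per_burst, pulse_freq) for f in freqs
    )
    if spacing <= longest:
        raise ValueError(
            f"spacing {spacing} s must exceed the longest trial duration {longest:.3f} s"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(freqs, trials_per_freq))
    events = []
    onset_s = start_s
    for f in order:
        onset = int(round(onset_s * fs))
        dur = trial_duration_s(f, bursts, pulses_per_burst, pulse_freq)
        offset = onset + int(round(dur * fs)) + 1  # first sample after last pulse
        events.append(
            StimEvent(
                onset=onset,
                offset=offset,
                burst_freq=float(f),
                inter_burst_interval_ms=round(1000.0 / f),
                pulse_freq=pulse_freq,
            )
        )
        onset_s += spacing + rng.uniform(-jitter, jitter)
    return StimSchedule(events, fs, pulses_per_burst=pulses_per_burst, bursts=bursts)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording session.

    ``source_gain_matrix`` (channels x latent sources) mixes shared pink
    sources into the channels and thereby controls inter-channel coherence;
    ``response_gain`` sets each channel's evoked-oscillation amplitude,
    proportional to its coupling to the stimulated site.
    """

    n_channels: int
    fs: float = 500.0
    duration_s: float | None = None
    background_exponent: float = 1.0
    source_gain_matrix: np.ndarray | None = None
    response_gain: np.ndarray | float = 0.0
    decay_tau: float = 0.5
    artifact_amplitude: float = 0.0
    artifact_channels: tuple[int, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        gain = np.broadcast_to(np.asarray(self.response_gain, float), (self.n_channels,))
        if (gain < 0).any():
            raise ValueError("response_gain must be non-negative elementwise")
        self.response_gain = np.array(gain)
        if self.source_gain_matrix is not None:
            m = np.asarray(self.source_gain_matrix, float)
            if m.ndim != 2 or m.shape[0] != self.n_channels:
                raise ValueError("source_gain_matrix must be (n_channels, n_sources)")
            self.source_gain_matrix = m


@dataclass
class GroundTruth:
    """Record of everything the simulator injected, for recovery tests."""

    trial_freqs: np.ndarray
    response_gain: np.ndarray
    decay_tau: float
    coupling: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trial": np.arange(len(self.trial_freqs)), "freq": self.trial_freqs})

    def gains_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": np.arange(len(self.response_gain)), "response_gain": self.response_gain}
        )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float, alpha: float) -> np.ndarray:
    """Rows of unit-variance 1/f^alpha noise via spectral shaping of white noise."""
    n_rows, n = shape
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal((n_rows, freqs.size)) + 1j * rng.standard_normal((n_rows, freqs.size)))
    x = np.fft.irfft(spec * shaping, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pulse_times_s(ev: StimEvent, schedule: StimSchedule) -> np.ndarray:
    ibi_s = ev.inter_burst_interval_ms / 1000.0
    onset_s = ev.onset / schedule.fs
    bursts = np.arange(schedule.bursts) * ibi_s
    pulses = np.arange(schedule.pulses_per_burst) / ev.pulse_freq
    return (onset_s + bursts[:, None] + pulses[None, :]).ravel()


def synthesize_recording(
    config: SimulationConfig, schedule: StimSchedule
) -> tuple[Recording, GroundTruth]:
    """Generate a recording for a schedule; returns the recording and its ground truth."""
    fs = config.fs
    if schedule.fs != fs:
        schedule = schedule.at_rate(fs)
    tail_s = 2.0 + 5.0 * config.decay_tau
    needed_s = (schedule.offsets.max() / fs + tail_s) if schedule.n_trials else 4.0
    duration_s = config.duration_s if config.duration_s is not None else needed_s
    n = int(round(duration_s * fs))
    if schedule.n_trials and schedule.offsets.max() + int(round(2.0 * fs)) > n:
        raise ValueError(
            f"schedule extends to {schedule.offsets.max() / fs:.1f} s, beyond the requested "
            f"duration of {duration_s:.1f} s"
        )
    rng = np.random.default_rng(config.seed)
    alpha = config.background_exponent

    signal = config.noise_sd * _pink_noise(rng, (config.n_channels, n), fs, alpha)
    if config.source_gain_matrix is not None and config.source_gain_matrix.shape[1] > 0:
        n_src = config.source_gain_matrix.shape[1]
        sources = _pink_noise(rng, (n_src, n), fs, alpha)
        signal += config.source_gain_matrix @ sources

    t = np.arange(n) / fs
    gain = config.response_gain
    for ev in schedule.events:
        onset_s, offset_s = ev.onset / fs, ev.offset / fs
        stop = min(n, ev.offset + int(round(8.0 * config.decay_tau * fs)))
        if ev.onset >= n:
            continue
        seg = slice(ev.onset, stop)
        tt = t[seg] - onset_s
        envelope = np.ones_like(tt)
        ramp_s = 1.0 / ev.burst_freq  # one burst period
        envelope = np.minimum(tt / ramp_s, 1.0)
        post = tt > (offset_s - onset_s)
        envelope[post] = envelope[~post][-1] if (~post).any() else 1.0
        envelope[post] *= np.exp(-(tt[post] - (offset_s - onset_s)) / config.decay_tau)
        wave = envelope * np.sin(2 * np.pi * ev.burst_freq * tt)  # phase 0 at onset
        signal[:, seg] += gain[:, None] * wave[None, :]

    if config.artifact_amplitude and config.artifact_channels:
        chans = np.asarray(config.artifact_channels, int)
        for ev in schedule.events:
            for pt in _pulse_times_s(ev, schedule):
                idx = int(round(pt * fs))
                if ev.onset <= idx < ev.offset:
                    signal[chans, idx] += config.artifact_amplitude
                    if idx + 1 < ev.offset:  # biphasic return, still inside the trial
                        signal[chans, idx + 1] -= config.artifact_amplitude

    channels = [
        ChannelInfo(label=f"CH{i:03d}", coords=(float(i * 10), 0.0, 0.0))
        for i in range(config.n_channels)
    ]
    rec = Recording(signal, fs, channels)
    truth = GroundTruth(
        trial_freqs=schedule.trial_freqs,
        response_gain=np.array(config.response_gain),
        decay_tau=config.decay_tau,
        coupling=None if config.source_gain_matrix is None else np.array(config.source_gain_matrix),
    )
    return rec, truth


def baseline_spans(
    schedule: StimSchedule, n_periods: int = 10, span_s: float = 10.0, gap_s: float = 1.0
) -> list[tuple[float, float]]:
    """Baseline 10-s periods taken from the quiet interval before the first trial."""
    first_onset_s = schedule.onsets.min() / schedule.fs if schedule.n_trials else math.inf
    spans = []
    t0 = 0.0
    for _ in range(n_periods):
        t1 = t0 + span_s
        if t1 > first_onset_s - gap_s:
            raise ValueError(
                f"{n_periods} baseline periods of {span_s} s do not fit before the first "
                f"trial at {first_onset_s:.1f} s"
            )
        spans.append((t0, t1))
        t0 = t1
    return spans


@dataclass
class SubjectSession:
    """One synthetic stimulation session of a cohort subject."""

    subject: int
    session: int
    recording: Recording
    schedule: StimSchedule
    ground_truth: GroundTruth
    stim_channel: int
    coupling_to_site: np.ndarray
    baseline: list[tuple[float, float]] = field(default_factory=list)


def coupled_cohort(
    n_subjects: int,
    template: SimulationConfig,
    coupling_response_corr: float,
    seed: int = 0,
    n_sessions: int = 2,
    stim_channel: int = 0,
    schedule_kwargs: dict | None = None,
    gain_scale: float = 3.0,
    baseline_periods: int = 10,
    baseline_span_s: float = 10.0,
) -> list[SubjectSession]:
    """Cohort with a known correlation between site coupling and evoked gain.

    Each subject gets a latent "stimulation-site" source with per-channel
    weights (its coupling profile, which sets coherence to the stimulated
    virtual electrode), and per-session evoked gains constructed so that the
    standardized gains correlate with the standardized couplings at
    ``coupling_response_corr``. The stimulated channel is flagged ``stimulated``
    and carries no evoked response, mirroring the convention that stimulated
    electrodes never enter the analysis.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rho = float(coupling_response_corr)
    if abs(rho) > 1:
        raise ValueError("coupling-response correlation must lie in [-1, 1]")
    root = np.random.default_rng(seed)
    schedule_kwargs = dict(schedule_kwargs or {})
    schedule_kwargs.setdefault("freqs", [3, 4, 5, 6, 7, 8])
    schedule_kwargs.setdefault("trials_per_freq", 60)
    start_s = baseline_periods * baseline_span_s + 2.0
    sessions: list[SubjectSession] = []
    n_ch = template.n_channels
    rec_mask = np.arange(n_ch) != stim_channel
    for subj in range(n_subjects):
        coupling = np.ones(n_ch)
        coupling[rec_mask] = root.uniform(0.1, 1.0, size=rec_mask.sum())
        src_gain = coupling[:, None]  # one shared site source
        zc = (coupling[rec_mask] - coupling[rec_mask].mean()) / coupling[rec_mask].std()
        for sess in range(n_sessions):
            eps = root.standard_normal(rec_mask.sum())
            eps = (eps - eps.mean()) / eps.std()
            latent = rho * zc + math.sqrt(1 - rho**2) * eps
            gains = np.zeros(n_ch)
            # scale by the channel's background SD (independent noise + shared
            # source) so the per-channel SNR — and hence the power t — tracks
            # the latent variable alone; otherwise high-coupling channels would
            # show systematically smaller log-power changes and the rho = 0
            # construction would not be a true null
            bg_sd = np.sqrt(template.noise_sd**2 + coupling[rec_mask] ** 2)
            gains[rec_mask] = np.clip(gain_scale * (1.0 + 0.4 * latent), 0.0, None) * bg_sd
            sched_seed = int(root.integers(2**31 - 1))
            sim_seed = int(root.integers(2**31 - 1))
            schedule = generate_schedule(
                fs=template.fs, seed=sched_seed, start_s=start_s, **schedule_kwargs
            )
            config = replace(
                template,
                source_gain_matrix=src_gain,
                response_gain=gains,
                seed=sim_seed,
            )
            rec, truth = synthesize_recording(config, schedule)
            rec.channels[stim_channel].excluded = "stimulated"
            sessions.append(
                SubjectSession(
                    subject=subj,
                    session=subj * n_sessions + sess,
                    recording=rec,
                    schedule=schedule,
                    ground_truth=truth,
                    stim_channel=stim_channel,
                    coupling_to_site=coupling,
                    baseline=baseline_spans(schedule, baseline_periods, baseline_span_s),
                )
            )
    return sessions
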