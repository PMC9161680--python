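"""Time-resolved theta power around stimulation trials.

Power is obtained by convolution with short multitaper windows (2 cycles per
frequency, time-bandwidth product 2) so that the stimulation interval cannot
leak far into the flanking windows. The per-trial time-frequency response is
averaged over 3-8 Hz, averaged over trials, and z-scored against the 500 ms
pre-onset baseline of the trial-averaged trace. The theta decay time is the
interval from the last stimulation pulse until that z trace first falls
below 1; electrodes whose z never reaches 2 are excluded, and traces that
stay above 1 throughout the 1-s post window are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import Recording, StimSchedule, resample_recording
from .spectral import _psd_stack, prepost_tstat

THETA_FREQS = np.arange(3.0, 9.0)


def tfr_convolve(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray = THETA_FREQS,
    n_cycles: float = 2.0,
    time_bandwidth: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolutional multitaper time-frequency power.

    ``signal`` is (n_samples,) or (n_trials, n_samples); returns ``(power,
    valid)`` with power shaped (n_trials, n_freqs, n_samples) (leading axis
    dropped for 1-D input) and ``valid`` a (n_freqs, n_samples) mask that is
    False within half a convolution window of either edge, where the estimate
    is contaminated by the boundary.
    """
    from mne.time_frequency import tfr_array_multitaper

    signal = np.asarray(signal, float)
    squeeze = signal.ndim == 1
    if squeeze:
        signal = signal[None, :]
    freqs = np.asarray(freqs, float)
    n = signal.shape[-1]
    max_win = int(np.ceil(n_cycles / freqs.min() * fs))
    if n < max_win:
        raise ValueError(
            f"trace of {n} samples is shorter than one {n_cycles}-cycle window of "
            f"{freqs.min()} Hz ({max_win} samples); provide more padding"
        )
    power = tfr_array_multitaper(
        signal[:, None, :],
        fs,
        freqs,
        n_cycles=n_cycles,
        time_bandwidth=time_bandwidth,
        output="power",
        zero_mean=False,
        verbose="error",
    )[:, 0]  # (n_trials, n_freqs, n_samples)
    half = np.ceil(n_cycles / freqs * fs / 2).astype(int)
    valid = np.zeros((freqs.size, n), dtype=bool)
    for i, h in enumerate(half):
        valid[i, h : n - h] = True
    if squeeze:
        power = power[0]
    return power, valid


@dataclass
class ThetaTimecourse:
    """Trial-averaged, baseline z-scored 3-8 Hz power versus time."""

    times: np.ndarray  # seconds relative to stimulation onset
    z: np.ndarray
    baseline: tuple[float, float]
    last_pulse_time: float
    decay_time: float | None = None
    decay_status: str = "unset"  # ok | censored | excluded | unset


def theta_z_timecourse(
    trial_power: np.ndarray,
    times: np.ndarray,
    last_pulse_time: float,
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> ThetaTimecourse:
    """Average over frequency then trials, z-score to the pre-onset baseline.

    The baseline mean and SD are those of the trial-averaged trace within the
    baseline window, so the decay criterion "within 1 SD of baseline" refers
    to the averaged signal.
    """
    trial_power = np.asarray(trial_power, float)
    if trial_power.ndim != 3 or trial_power.shape[0] < 2:
        raise ValueError("trial_power must be (n_trials >= 2, n_freqs, n_times)")
    times = np.asarray(times, float)
    mean_trace = trial_power.mean(axis=1).mean(axis=0)  # freq mean, then trial mean
    in_base = (times >= baseline[0]) & (times < baseline[1])
    if not in_base.any():
        raise ValueError("baseline window contains no samples")
    mu = mean_trace[in_base].mean()
    sd = mean_trace[in_base].std()
    if sd == 0:
        raise ValueError("baseline SD is zero; z-scoring is ill-posed")
    z = (mean_trace - mu) / sd
    return ThetaTimecourse(times=times, z=z, baseline=baseline, last_pulse_time=last_pulse_time)


def decay_time(
    tc: ThetaTimecourse,
    post_window_s: float = 1.0,
    inclusion_z: float = 2.0,
    return_z: float = 1.0,
) -> ThetaTimecourse:
    """Annotate a timecourse with its theta decay time.

    Decay time is the interval from the last pulse until z first falls below
    ``return_z`` (resolved at sample resolution). Electrodes whose z never
    exceeds ``inclusion_z`` anywhere are marked ``excluded``; traces that never
    return within ``post_window_s`` of the last pulse are ``censored`` and are
    left out of summary statistics.
    """
    if tc.z.max() < inclusion_z:
        tc.decay_time, tc.decay_status = None, "excluded"
        return tc
    t0 = tc.last_pulse_time
    eps = 1e-9  # tolerate float rounding of the time grid
    sel = (tc.times >= t0 - eps) & (tc.times <= t0 + post_window_s + eps)
    if not sel.any():
        raise ValueError("no samples in the post-stimulation window")
    t_post = tc.times[sel]
    z_post = tc.z[sel]
    below = np.nonzero(z_post < return_z)[0]
    if below.size == 0:
        tc.decay_time, tc.decay_status = None, "censored"
        return tc
    tc.decay_time = max(float(t_post[below[0]] - t0), 0.0)
    tc.decay_status = "ok"
    return tc


def peak_frequency(tfr: np.ndarray, freqs: np.ndarray = THETA_FREQS) -> np.ndarray:
    """Per-sample frequency of maximum spectral power (unsmoothed)."""
    tfr = np.asarray(tfr, float)
    return np.asarray(freqs, float)[tfr.argmax(axis=-2)]


def electrode_timecourses(
    rec: Recording,
    schedule: StimSchedule,
    analysis_fs: float = 50.0,
    pad_s: float = 1.5,
    post_s: float = 1.5,
    baseline: tuple[float, float] = (-0.5, 0.0),
    freqs: np.ndarray = THETA_FREQS,
    by_freq: bool = False,
) -> dict:
    """Theta z timecourses for every good channel (optionally per stimulation frequency).

    Trials are cut with ``pad_s`` of pre-onset and ``post_s`` of post-offset
    padding, convolved, and aligned on stimulation onset. Because trial
    durations differ across burst frequencies, trials are grouped by
    frequency for the convolution and the grand average weights each
    frequency group equally after aligning on onset.
    """
    if analysis_fs < rec.fs:
        rec = resample_recording(rec, analysis_fs)
    schedule = schedule.at_rate(rec.fs)
    fs = rec.fs
    good = rec.good_indices()
    results: dict = {}
    freq_groups = schedule.freq_set()
    for ch in good:
        per_freq = {}
        for f in freq_groups:
            evs = [e for e in schedule.events if e.burst_freq == f]
            n_pre = int(round(pad_s * fs))
            durations = {e.offset - e.onset for e in evs}
            n_dur = max(durations)
            n_post = int(round(post_s * fs))
            traces = []
            for e in evs:
                start, stop = e.onset - n_pre, e.onset + n_dur + n_post
                if start < 0 or stop > rec.n_samples:
                    continue
                traces.append(rec.signal[ch, start:stop])
            if len(traces) < 2:
                raise ValueError(f"fewer than 2 usable trials at {f} Hz")
            stack = np.stack(traces)
            power, _ = tfr_convolve(stack, fs, freqs)
            times = (np.arange(stack.shape[1]) - n_pre) / fs
            last_pulse = (n_dur - 1) / fs
            tc = theta_z_timecourse(power, times, last_pulse, baseline)
            per_freq[f] = decay_time(tc)
        if by_freq:
            results[rec.channels[ch].label] = per_freq
        else:
            # average z traces across frequency groups on a common onset-aligned axis
            n_common = min(tc.z.size for tc in per_freq.values())
            z = np.mean([tc.z[:n_common] for tc in per_freq.values()], axis=0)
            times = next(iter(per_freq.values())).times[:n_common]
            last_pulse = float(np.mean([tc.last_pulse_time for tc in per_freq.values()]))
            merged = ThetaTimecourse(times, z, baseline, last_pulse)
            results[rec.channels[ch].label] = decay_time(merged)
    return results


def decay_summary(results: dict) -> pd.DataFrame:
    """Decay-time table with status column; censored/excluded carry no value."""
    rows = []
    for label, tc in results.items():
        if isinstance(tc, dict):
            for f, t in tc.items():
                rows.append(
                    {"label": label, "stim_freq": f, "decay_time_s": t.decay_time, "status": t.decay_status}
                )
        else:
            rows.append(
                {"label": label, "stim_freq": None, "decay_time_s": tc.decay_time, "status": tc.decay_status}
            )
    return pd.DataFrame(rows)


def during_tstats(
    rec: Recording,
    schedule: StimSchedule,
    analysis_fs: float = 50.0,
    band: tuple[float, float] = (3.0, 8.0),
    tbw: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """During- and post-stimulation band t per electrode and stimulation frequency.

    For each burst frequency the during window is the stimulation interval of
    that trial type and the matched pre window is the same duration ending at
    onset; the post t uses an equal-duration window starting at offset. Both
    use single (non-sliding) multitaper windows so there is no temporal
    leakage between intervals. Returns (during_t, post_t, freq_list) with
    arrays shaped (n_good_channels, n_freqs).
    """
    if analysis_fs < rec.fs:
        rec = resample_recording(rec, analysis_fs)
    schedule = schedule.at_rate(rec.fs)
    fs = rec.fs
    good = rec.good_indices()
    freq_list = schedule.freq_set()
    fgrid = np.arange(band[0], band[1] + 0.5)
    during_t = np.zeros((good.size, len(freq_list)))
    post_t = np.zeros_like(during_t)
    for j, f in enumerate(freq_list):
        evs = [e for e in schedule.events if e.burst_freq == f]
        n_dur = max(e.offset - e.onset for e in evs)
        pre = np.stack([rec.signal[good, e.onset - n_dur : e.onset] for e in evs])
        dur = np.stack([rec.signal[good, e.onset : e.onset + n_dur] for e in evs])
        post = np.stack([rec.signal[good, e.offset : e.offset + n_dur] for e in evs])
        p_pre, _ = _psd_stack(pre, fs, fgrid, tbw, 0.9)
        p_dur, _ = _psd_stack(dur, fs, fgrid, tbw, 0.9)
        p_post, _ = _psd_stack(post, fs, fgrid, tbw, 0.9)
        for k in range(good.size):
            during_t[k, j] = prepost_tstat(p_pre[:, k], p_dur[:, k])
            post_t[k, j] = prepost_tstat(p_pre[:, k], p_post[:, k])
    return during_t, post_t, freq_list


def during_post_coupling(during_t: np.ndarray, post_t: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of during- vs post-stimulation t values with a
    circular-shift permutation p-value.

    Flattens the (electrode x stimulation-frequency) matrices to vectors; the
    permutation null preserves the serial dependence between neighboring
    entries, correcting for non-independence across electrodes and
    frequencies.
    """
    from .inference import circular_shift_permutation

    x = np.asarray(during_t, float).ravel()
    y = np.asarray(post_t, float).ravel()
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 paired values with matching shapes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(pearsonr(x, y).statistic)
    null = circular_shift_permutation(x, y)
    return r, null.p_value
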