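"""Multitaper PSD estimation and pre/post paired power statistics.

Spectral power in fixed windows is estimated with Slepian (DPSS) tapers:
power is averaged (unweighted) over the tapers whose spectral concentration
(eigenvalue) reaches the threshold, 0.90 by default. Electrode-level effects
are paired t-statistics over trials on log power averaged within a band;
positive t means power increased after stimulation.

Analysis bands follow the standard convention: theta 3-8, alpha 9-13, beta
16-28, gamma 30-50, and high-frequency broadband (HFB) 75-200 Hz. Theta
analyses run at a 50 Hz sampling rate; higher bands at 100 or 500 Hz. For
non-theta bands the 100 ms flanking the stimulation interval are excluded to
keep pulse artifact out of the windows, and any electrode whose theta t
exceeds 5 is dropped from those summaries as likely signal corruption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .io import Recording, StimSchedule, resample_recording, segment_trials

#: band name -> (fmin, fmax, analysis sampling rate)
BANDS: dict[str, tuple[float, float, float]] = {
    "theta": (3.0, 8.0, 50.0),
    "alpha": (9.0, 13.0, 100.0),
    "beta": (16.0, 28.0, 100.0),
    "gamma": (30.0, 50.0, 500.0),
    "hfb": (75.0, 200.0, 500.0),
}

RESPONDER_T = 2.0
HF_EXCLUSION_T = 5.0

#: time-bandwidth product for the frequency-resolved (1-Hz sense bin) analysis.
#: Band-level statistics use tbw = 3, but on a 1-s window that taper family is
#: concentrated over +/- 3 Hz and cannot separate neighboring 1-Hz bins; the
#: per-bin statistics therefore use a single NW = 1 Slepian whose half-bandwidth
#: matches the bin spacing.
SENSE_TBW = 1.0


def dpss_tapers(
    n: int, tbw: float, concentration_min: float = 0.9, max_tapers: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Slepian tapers of length ``n`` with eigenvalue >= ``concentration_min``."""
    if tbw < 1:
        raise ValueError("time-bandwidth product must be >= 1")
    kmax = max_tapers if max_tapers is not None else max(int(2 * tbw) - 1, 1)
    tapers, ratios = dpss(n, tbw, Kmax=kmax, return_ratios=True)
    tapers = np.atleast_2d(tapers)
    ratios = np.atleast_1d(ratios)
    keep = ratios >= concentration_min
    if not keep.any():
        raise ValueError(
            f"no taper reaches spectral concentration {concentration_min} "
            f"(max eigenvalue {ratios.max():.3f})"
        )
    return tapers[keep], ratios[keep]


@dataclass
class PSD:
    """Multitaper power spectral density on a fixed frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    tapers_used: int


def _psd_stack(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    tbw: float,
    concentration_min: float,
    max_tapers: int | None = None,
) -> tuple[np.ndarray, int]:
    """Multitaper PSD of ``x`` (..., n) at the requested frequencies."""
    n = x.shape[-1]
    tapers, _ = dpss_tapers(n, tbw, concentration_min, max_tapers)
    fft_freqs = np.fft.rfftfreq(n, 1.0 / fs)
    bins = np.array([np.argmin(np.abs(fft_freqs - f)) for f in freqs])
    tapered = x[..., None, :] * tapers  # (..., K, n)
    spec = np.fft.rfft(tapered, axis=-1)[..., bins]
    # tapers are unit-energy, so the one-sided density is 2|X|^2 / fs
    power = (np.abs(spec) ** 2).mean(axis=-2) * (2.0 / fs)
    return power, tapers.shape[0]


def multitaper_psd(
    segment: np.ndarray,
    fs: float,
    band: tuple[float, float] = (3.0, 8.0),
    step: float = 1.0,
    tbw: float = 3.0,
    concentration_min: float = 0.9,
) -> PSD:
    """Multitaper PSD of one window on a ``step``-Hz grid within ``band``."""
    segment = np.asarray(segment, float)
    if segment.ndim != 1:
        raise ValueError("segment must be 1-D; use the batched helpers for stacks")
    fmin, fmax = band
    if fmax > fs / 2:
        raise ValueError(f"band upper edge {fmax} Hz exceeds Nyquist {fs / 2} Hz")
    if segment.size / fs < 2.0 / fmin:
        raise ValueError(
            f"window of {segment.size / fs:.3f} s holds fewer than 2 cycles of {fmin} Hz"
        )
    freqs = np.arange(fmin, fmax + step / 2, step)
    power, k = _psd_stack(segment, fs, freqs, tbw, concentration_min)
    return PSD(frequencies=freqs, power=power, tapers_used=k)


def _paired_t(diffs: np.ndarray) -> float:
    """Paired t with the degenerate-variance limit: signed infinity, 0 for ties at 0."""
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 trials")
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0
        return math.copysign(math.inf, mean)
    return float(mean / (sd / math.sqrt(n)))


def prepost_tstat(pre_powers: np.ndarray, post_powers: np.ndarray) -> float:
    """Band t-statistic: log power, band mean per trial, paired t of post vs pre."""
    pre = np.asarray(pre_powers, float)
    post = np.asarray(post_powers, float)
    if pre.shape != post.shape:
        raise ValueError("pre and post power arrays must have identical shape")
    if pre.ndim == 1:
        pre, post = pre[:, None], post[:, None]
    if (pre <= 0).any() or (post <= 0).any():
        raise ValueError("power values must be strictly positive for log transform")
    diffs = np.log(post).mean(axis=1) - np.log(pre).mean(axis=1)
    return _paired_t(diffs)


def per_frequency_tstats(pre_powers: np.ndarray, post_powers: np.ndarray) -> np.ndarray:
    """Paired t at each frequency bin separately (columns of trials x freqs)."""
    pre = np.asarray(pre_powers, float)
    post = np.asarray(post_powers, float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("expected matching 2-D (trials x freqs) arrays")
    if (pre <= 0).any() or (post <= 0).any():
        raise ValueError("power values must be strictly positive for log transform")
    d = np.log(post) - np.log(pre)
    return np.array([_paired_t(d[:, j]) for j in range(d.shape[1])])


def trial_band_powers(
    rec: Recording,
    schedule: StimSchedule,
    fmin: float,
    fmax: float,
    analysis_fs: float | None = None,
    margin_s: float = 0.0,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    step: float = 1.0,
    tbw: float = 3.0,
    concentration_min: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial multitaper power in pre and post windows for every channel.

    Returns ``(freqs, pre_power, post_power)`` with power arrays shaped
    (n_channels, n_trials, n_freqs). The recording is resampled to
    ``analysis_fs`` first (never upsampled).
    """
    if analysis_fs is not None and analysis_fs < rec.fs:
        rec = resample_recording(rec, analysis_fs)
    segs = segment_trials(rec, schedule, pre_s=pre_s, post_s=post_s, margin_s=margin_s)
    freqs = np.arange(fmin, fmax + step / 2, step)
    if fmax > rec.fs / 2:
        raise ValueError(f"band upper edge {fmax} Hz exceeds Nyquist {rec.fs / 2} Hz")
    out = []
    for which in ("pre", "post"):
        stack = segs.extract(rec.signal, which)  # (n_trials, n_ch, n)
        power, _ = _psd_stack(stack, rec.fs, freqs, tbw, concentration_min)
        out.append(np.swapaxes(power, 0, 1))  # -> (n_ch, n_trials, n_freqs)
    return freqs, out[0], out[1]


@dataclass
class ElectrodeStats:
    """Per-electrode stimulation-response statistics."""

    label: str
    band_t: float
    sense_t: np.ndarray | None = None  # t per 1-Hz theta bin
    stim_t: dict[float, float] = field(default_factory=dict)  # t per stimulation frequency
    responder: str = "none"
    hf_excluded: bool = False


def classify_responders(
    stats: list[ElectrodeStats],
    threshold: float = RESPONDER_T,
    hf_threshold: float = HF_EXCLUSION_T,
) -> dict:
    """Label electrodes responsive (t > 2), negative (t < -2), or none.

    Electrodes with theta t above the high-frequency exclusion threshold are
    additionally flagged; they keep their responder label for theta summaries
    but are dropped from non-theta band analyses.
    """
    for s in stats:
        if s.band_t > threshold:
            s.responder = "responsive"
        elif s.band_t < -threshold:
            s.responder = "negative"
        else:
            s.responder = "none"
        s.hf_excluded = s.band_t > hf_threshold
    n = len(stats)
    counts = {
        "responsive": sum(s.responder == "responsive" for s in stats),
        "negative": sum(s.responder == "negative" for s in stats),
        "none": sum(s.responder == "none" for s in stats),
        "hf_excluded": sum(s.hf_excluded for s in stats),
        "total": n,
    }
    counts["prop_responsive"] = counts["responsive"] / n if n else float("nan")
    counts["prop_negative"] = counts["negative"] / n if n else float("nan")
    return counts


def electrode_stats(
    rec: Recording,
    schedule: StimSchedule,
    band: str = "theta",
    margin_s: float | None = None,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    tbw: float = 3.0,
    sense_tbw: float = SENSE_TBW,
    theta_band_t: np.ndarray | None = None,
) -> list[ElectrodeStats]:
    """Band t-statistics for every non-excluded electrode.

    Theta runs with zero margin; other bands default to a 100 ms margin and
    require ``theta_band_t`` (aligned with the good channels) so that
    electrodes with theta t > 5 can be dropped from the summary. Band-level
    and per-stimulation-frequency t use ``tbw``; the per-1-Hz sense-bin t
    uses the narrower ``sense_tbw`` family (see :data:`SENSE_TBW`).
    """
    if band not in BANDS:
        raise KeyError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    fmin, fmax, analysis_fs = BANDS[band]
    if margin_s is None:
        margin_s = 0.0 if band == "theta" else 0.1
    good = rec.good_indices()
    freqs, pre_p, post_p = trial_band_powers(
        rec, schedule, fmin, fmax, analysis_fs, margin_s, pre_s, post_s, tbw=tbw
    )
    if band == "theta":
        _, pre_s_p, post_s_p = trial_band_powers(
            rec, schedule, fmin, fmax, analysis_fs, margin_s, pre_s, post_s, tbw=sense_tbw
        )
    trial_freqs = schedule.trial_freqs
    stats: list[ElectrodeStats] = []
    for k, ch in enumerate(good):
        if band != "theta" and theta_band_t is not None and theta_band_t[k] > HF_EXCLUSION_T:
            continue
        band_t = prepost_tstat(pre_p[ch], post_p[ch])
        st = ElectrodeStats(label=rec.channels[ch].label, band_t=band_t)
        if band == "theta":
            st.sense_t = per_frequency_tstats(pre_s_p[ch], post_s_p[ch])
            for f in sorted(set(trial_freqs)):
                sel = trial_freqs == f
                st.stim_t[float(f)] = prepost_tstat(pre_p[ch][sel], post_p[ch][sel])
        stats.append(st)
    classify_responders(stats)
    return stats


def stats_frame(stats: list[ElectrodeStats]) -> pd.DataFrame:
    """Tabular view of electrode statistics for CSV export."""
    rows = []
    for s in stats:
        row = {
            "label": s.label,
            "band_t": s.band_t,
            "responder": s.responder,
            "hf_excluded": s.hf_excluded,
        }
        if s.sense_t is not None:
            for f, t in zip(range(3, 3 + len(s.sense_t)), s.sense_t):
                row[f"sense_t_{f}Hz"] = t
        for f, t in s.stim_t.items():
            row[f"stim_t_{f:g}Hz"] = t
        rows.append(row)
    return pd.DataFrame(rows)
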