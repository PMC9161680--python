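"""Data model, file I/O, and trial segmentation for stimulation recordings.

A :class:`Recording` holds an already-referenced multichannel signal matrix
(channels x samples, microvolt scale) with per-channel metadata; stimulation
events are kept in a :class:`StimSchedule` of :class:`StimEvent` entries tied
to a sampling rate. Windows are half-open ``[start, stop)`` sample-index
ranges; sample indices are 0-based throughout.

Native on-disk container is HDF5 (signal matrix + JSON channel metadata) with
a CSV event sidecar; EDF import goes through :mod:`mne`, and a minimal EDF
writer is provided for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

EXCLUSION_REASONS = ("none", "non-physiologic", "ictal", "seizure-onset-zone", "stimulated")

#: columns of the event sidecar CSV
EVENT_COLUMNS = (
    "onset_s",
    "offset_s",
    "burst_freq",
    "inter_burst_interval_ms",
    "pulse_freq",
    "amplitude_ma",
)


@dataclass
class ChannelInfo:
    """Label, 3-D coordinates in mm, and exclusion flag for one channel."""

    label: str
    coords: tuple[float, float, float] = (0.0, 0.0, 0.0)
    excluded: str = "none"

    def __post_init__(self) -> None:
        if self.excluded not in EXCLUSION_REASONS:
            raise ValueError(
                f"unknown exclusion reason {self.excluded!r}; expected one of {EXCLUSION_REASONS}"
            )
        self.coords = tuple(float(c) for c in self.coords)
        if len(self.coords) != 3:
            raise ValueError("coords must be 3-D (mm)")

    @property
    def is_good(self) -> bool:
        return self.excluded == "none"

    @property
    def coherence_ok(self) -> bool:
        """Usable in baseline coherence networks.

        Stimulated channels are excluded from all per-electrode power
        analyses, but their baseline (pre-task) signal is clean and they are
        the site term of the connectivity analyses; only quality exclusions
        mask a channel out of the network.
        """
        return self.excluded in ("none", "stimulated")


@dataclass
class Recording:
    """Multichannel referenced trace: ``signal`` (channels x samples) at ``fs`` Hz."""

    signal: np.ndarray
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel records for {self.signal.shape[0]} signal rows"
            )
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaN")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def good_indices(self) -> np.ndarray:
        """Indices of channels not excluded for any reason."""
        return np.array([i for i, c in enumerate(self.channels) if c.is_good], dtype=int)

    def coords(self) -> np.ndarray:
        return np.array([c.coords for c in self.channels], dtype=float)


@dataclass
class StimEvent:
    """One stimulation trial: sample-index onset/offset plus burst parameters.

    ``offset`` is the first sample index after the last pulse, so the during
    window is ``[onset, offset)`` and the post window starts at ``offset``.
    """

    onset: int
    offset: int
    burst_freq: float
    inter_burst_interval_ms: int
    pulse_freq: float = 100.0
    amplitude_ma: float = 0.5

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")
        if self.burst_freq <= 0:
            raise ValueError("burst_freq must be positive")
        expected = round(1000.0 / self.burst_freq)
        if self.inter_burst_interval_ms != expected:
            raise ValueError(
                f"inter-burst interval {self.inter_burst_interval_ms} ms inconsistent with "
                f"{self.burst_freq} Hz (expected {expected} ms)"
            )


@dataclass
class StimSchedule:
    """Ordered stimulation trials tied to a sampling rate."""

    events: list[StimEvent]
    fs: float
    pulses_per_burst: int = 5
    bursts: int = 5

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=int)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.events], dtype=int)

    @property
    def trial_freqs(self) -> np.ndarray:
        return np.array([e.burst_freq for e in self.events], dtype=float)

    def freq_set(self) -> list[float]:
        return sorted(set(e.burst_freq for e in self.events))

    def at_rate(self, new_fs: float) -> "StimSchedule":
        """Rescale event sample indices to a new sampling rate."""
        if new_fs == self.fs:
            return self
        scale = new_fs / self.fs
        events = [
            replace(
                e,
                onset=int(round(e.onset * scale)),
                offset=max(int(round(e.offset * scale)), int(round(e.onset * scale)) + 1),
            )
            for e in self.events
        ]
        return StimSchedule(events, new_fs, self.pulses_per_burst, self.bursts)

    def last_pulse_times(self) -> np.ndarray:
        """Time of the last pulse of each trial, in seconds."""
        return (self.offsets - 1) / self.fs


@dataclass
class TrialWindow:
    pre: tuple[int, int]
    during: tuple[int, int]
    post: tuple[int, int]


@dataclass
class TrialSegments:
    """Half-open index windows around each stimulation trial.

    With a nonzero artifact margin the pre window ends ``margin_s`` before
    onset and the post window starts ``margin_s`` after offset, shrinking the
    fixed-duration windows only on the stimulation side.
    """

    windows: list[TrialWindow]
    fs: float
    pre_s: float
    post_s: float
    margin_s: float

    @property
    def n_trials(self) -> int:
        return len(self.windows)

    def extract(self, signal: np.ndarray, which: str) -> np.ndarray:
        """Stack one window type across trials -> (n_trials, n_channels, n_samples).

        Requires all windows of that type to have equal length (true for pre
        and post; during-window lengths vary across burst frequencies).
        """
        spans = [getattr(w, which) for w in self.windows]
        lengths = {stop - start for start, stop in spans}
        if len(lengths) > 1:
            raise ValueError(f"{which} windows have unequal lengths {sorted(lengths)}")
        return np.stack([signal[..., start:stop] for start, stop in spans])


def segment_trials(
    rec: Recording,
    events: list[StimEvent] | StimSchedule,
    pre_s: float,
    post_s: float,
    margin_s: float = 0.0,
) -> TrialSegments:
    """Compute pre/during/post index windows for each stimulation trial."""
    if isinstance(events, StimSchedule):
        if events.fs != rec.fs:
            events = events.at_rate(rec.fs)
        events = events.events
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be positive")
    if margin_s < 0:
        raise ValueError("margin_s must be non-negative")
    if margin_s >= min(pre_s, post_s):
        raise ValueError("margin_s must be smaller than the window durations")
    fs = rec.fs
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    n_margin = int(round(margin_s * fs))
    windows = []
    for i, ev in enumerate(events):
        pre = (ev.onset - n_pre, ev.onset - n_margin)
        post = (ev.offset + n_margin, ev.offset + n_post)
        during = (ev.onset, ev.offset)
        for name, (start, stop) in (("pre", pre), ("during", during), ("post", post)):
            if start < 0 or stop > rec.n_samples:
                raise ValueError(
                    f"trial {i} ({name} window [{start}, {stop})) falls outside the "
                    f"recording of {rec.n_samples} samples"
                )
        windows.append(TrialWindow(pre=pre, during=during, post=post))
    return TrialSegments(windows, fs, pre_s, post_s, margin_s)


def bipolar_rereference(raw: Recording, pairs: list[tuple[str, str]]) -> Recording:
    """Re-reference to a bipolar montage: one virtual electrode per adjacent pair.

    Each output channel is the difference of the pair members, positioned at
    their coordinate midpoint. Exclusion flags propagate: a pair containing an
    excluded member is excluded for the same reason.
    """
    index = {c.label: i for i, c in enumerate(raw.channels)}
    rows = []
    infos = []
    for a, b in pairs:
        for lab in (a, b):
            if lab not in index:
                raise KeyError(f"channel label {lab!r} not found in recording")
        ia, ib = index[a], index[b]
        rows.append(raw.signal[ia] - raw.signal[ib])
        ca, cb = raw.channels[ia], raw.channels[ib]
        mid = tuple((x + y) / 2.0 for x, y in zip(ca.coords, cb.coords))
        reason = ca.excluded if ca.excluded != "none" else cb.excluded
        infos.append(ChannelInfo(label=f"{a}-{b}", coords=mid, excluded=reason))
    return Recording(np.array(rows), raw.fs, infos)


def resample_recording(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased resampling of every channel to ``target_fs``."""
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    sig = resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    return Recording(sig, target_fs, list(rec.channels))


# ---------------------------------------------------------------------------
# Native HDF5 container + CSV event sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    import h5py

    meta = [
        {"label": c.label, "coords": list(c.coords), "excluded": c.excluded}
        for c in rec.channels
    ]
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["channels"] = json.dumps(meta)


def read_recording(path: str | Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        if "signal" not in f or "fs" not in f.attrs or "channels" not in f.attrs:
            raise ValueError(f"{path}: not a recording container (missing signal/fs/channels)")
        signal = f["signal"][()]
        fs = float(f.attrs["fs"])
        meta = json.loads(f.attrs["channels"])
    if len(meta) != signal.shape[0]:
        raise ValueError(
            f"{path}: header lists {len(meta)} channels but signal has {signal.shape[0]} rows"
        )
    chans = [ChannelInfo(m["label"], tuple(m["coords"]), m["excluded"]) for m in meta]
    return Recording(signal, fs, chans)


def write_events(schedule: StimSchedule, path: str | Path) -> None:
    fs = schedule.fs
    df = pd.DataFrame(
        {
            "onset_s": [e.onset / fs for e in schedule.events],
            "offset_s": [e.offset / fs for e in schedule.events],
            "burst_freq": [e.burst_freq for e in schedule.events],
            "inter_burst_interval_ms": [e.inter_burst_interval_ms for e in schedule.events],
            "pulse_freq": [e.pulse_freq for e in schedule.events],
            "amplitude_ma": [e.amplitude_ma for e in schedule.events],
        }
    )
    df.to_csv(path, index=False)


def read_events(path: str | Path, fs: float) -> StimSchedule:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: event sidecar missing columns {sorted(missing)}")
    events = [
        StimEvent(
            onset=int(round(r.onset_s * fs)),
            offset=int(round(r.offset_s * fs)),
            burst_freq=float(r.burst_freq),
            inter_burst_interval_ms=int(r.inter_burst_interval_ms),
            pulse_freq=float(r.pulse_freq),
            amplitude_ma=float(r.amplitude_ma),
        )
        for r in df.itertuples()
    ]
    return StimSchedule(events, fs)


# ---------------------------------------------------------------------------
# EDF interoperability
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> Recording:
    """Import an EDF file via mne. Coordinates default to the origin."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # mne returns volts for EEG channels
    chans = [ChannelInfo(label=name) for name in raw.ch_names]
    return Recording(sig, float(raw.info["sfreq"]), chans)


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a minimal single-record EDF file (16-bit, physical-range scaled)."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch, n_samp = rec.signal.shape
    record_dur = n_samp / fs
    phys_min = np.floor(rec.signal.min(axis=1))
    phys_max = np.ceil(rec.signal.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def _f(x: object, n: int) -> bytes:
        s = f"{x}"[:n]
        return s.ljust(n).encode("ascii")

    header = b"".join(
        [
            _f(0, 8),
            _f("thetaburst export", 80),
            _f("synthetic recording", 80),
            _f("01.01.00", 8),
            _f("00.00.00", 8),
            _f(256 * (n_ch + 1), 8),
            _f("", 44),
            _f(1, 8),
            _f(f"{record_dur:.6f}".rstrip("0").rstrip("."), 8),
            _f(n_ch, 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(_f(c.label[:16], 16) for c in rec.channels),
            b"".join(_f("", 80) for _ in range(n_ch)),
            b"".join(_f("uV", 8) for _ in range(n_ch)),
            b"".join(_f(f"{phys_min[i]:.0f}", 8) for i in range(n_ch)),
            b"".join(_f(f"{phys_max[i]:.0f}", 8) for i in range(n_ch)),
            b"".join(_f(dig_min, 8) for _ in range(n_ch)),
            b"".join(_f(dig_max, 8) for _ in range(n_ch)),
            b"".join(_f("", 80) for _ in range(n_ch)),
            b"".join(_f(n_samp, 8) for _ in range(n_ch)),
            b"".join(_f("", 32) for _ in range(n_ch)),
        ]
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((rec.signal - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(per_sig)
        f.write(digital.tobytes())  # one record: channels sequential
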