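"""Baseline coherence networks, distance residualization, and site-level correlates.

Coherence between electrodes x and y is the normalized magnitude of the
cross-spectral density,

    C_xy(f) = |S_xy(f)| / sqrt(S_xx(f) S_yy(f)),

estimated with DPSS multitapers on 1-s windows drawn sequentially from 10-s
baseline (non-stimulation) periods. Cross- and auto-spectra are averaged
across all windows and tapers first, normalized, and then averaged over the
5-13 Hz band.

Because nearby electrodes are densely connected (and volume conduction
inflates short-range coherence), logit-transformed coherence is regressed on
the normalized inter-electrode distance exp(-d) and the residuals serve as
distance-independent connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import logit
from scipy.stats import pearsonr

from .io import Recording
from .spectral import dpss_tapers

LOGIT_CLIP = 1e-6


@dataclass
class CrossSpectralEstimate:
    """Window- and taper-averaged spectral densities for all channel pairs."""

    freqs: np.ndarray
    s_cross: np.ndarray  # (n_ch, n_ch, n_freqs) complex, Hermitian in the channel axes
    n_windows: int
    n_tapers: int

    @property
    def s_auto(self) -> np.ndarray:
        return np.real(np.einsum("iif->if", self.s_cross))


@dataclass
class CoherenceNetwork:
    """Symmetric electrode x electrode coherence with optional residualization."""

    coherence: np.ndarray  # band-mean C in [0, 1]; NaN on the diagonal and masked rows
    labels: list[str]
    good: np.ndarray  # boolean mask of analyzable electrodes
    band: tuple[float, float]
    n_windows: int
    residual: np.ndarray | None = None  # distance-residualized logit coherence
    dist_norm: np.ndarray | None = None  # exp(-d), d in mm
    cross: CrossSpectralEstimate | None = None


def cross_spectra(
    windows: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    tbw: float = 4.0,
    max_tapers: int = 8,
    concentration_min: float = 0.9,
) -> CrossSpectralEstimate:
    """Average cross-spectral densities over windows and tapers.

    ``windows`` is (n_windows, n_channels, n_samples).
    """
    n_win, n_ch, n = windows.shape
    tapers, _ = dpss_tapers(n, tbw, concentration_min, max_tapers=max_tapers)
    fft_freqs = np.fft.rfftfreq(n, 1.0 / fs)
    bins = np.array([np.argmin(np.abs(fft_freqs - f)) for f in freqs])
    spec = np.fft.rfft(windows[:, :, None, :] * tapers, axis=-1)[..., bins]
    # mean over windows and tapers of X_i conj(X_j)
    s = np.einsum("wikf,wjkf->ijf", spec, np.conj(spec)) / (n_win * tapers.shape[0])
    return CrossSpectralEstimate(freqs=np.asarray(freqs, float), s_cross=s,
                                 n_windows=n_win, n_tapers=tapers.shape[0])


def baseline_coherence(
    rec: Recording,
    baseline_periods: list[tuple[float, float]],
    band: tuple[float, float] = (5.0, 13.0),
    window_s: float = 1.0,
    tbw: float = 4.0,
    max_tapers: int = 8,
    min_windows: int = 100,
) -> CoherenceNetwork:
    """Band-mean coherence network from sequential baseline windows.

    Each baseline period is cut into non-overlapping ``window_s`` windows;
    cross-spectra are averaged across every window before normalization.
    Pairs involving excluded channels are masked.
    """
    fs = rec.fs
    n_win_samples = int(round(window_s * fs))
    spans = []
    for start_s, stop_s in baseline_periods:
        a, b = int(round(start_s * fs)), int(round(stop_s * fs))
        if a < 0 or b > rec.n_samples:
            raise ValueError(f"baseline period [{start_s}, {stop_s}) s outside recording")
        for w0 in range(a, b - n_win_samples + 1, n_win_samples):
            spans.append((w0, w0 + n_win_samples))
    if len(spans) < min_windows:
        raise ValueError(
            f"only {len(spans)} baseline windows; at least {min_windows} required "
            "for network estimation"
        )
    windows = np.stack([rec.signal[:, a:b] for a, b in spans])
    freqs = np.arange(band[0], band[1] + 0.5)
    est = cross_spectra(windows, fs, freqs, tbw=tbw, max_tapers=max_tapers)
    s_auto = est.s_auto
    denom = np.sqrt(s_auto[:, None, :] * s_auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        c_f = np.abs(est.s_cross) / denom
    c = c_f.mean(axis=-1)
    good = np.array([ch.coherence_ok for ch in rec.channels])
    c[~good, :] = np.nan
    c[:, ~good] = np.nan
    np.fill_diagonal(c, np.nan)
    return CoherenceNetwork(
        coherence=c,
        labels=rec.labels,
        good=good,
        band=band,
        n_windows=est.n_windows,
        cross=est,
    )


def residualize_distance(net: CoherenceNetwork, coords: np.ndarray) -> CoherenceNetwork:
    """Regress logit coherence on normalized distance exp(-d); keep residuals.

    ``coords`` are per-electrode 3-D positions in mm. The residual matrix is
    symmetric with NaN wherever the coherence matrix is masked; by OLS
    construction the residuals are orthogonal to the predictor.
    """
    coords = np.asarray(coords, float)
    n = net.coherence.shape[0]
    if coords.shape != (n, 3):
        raise ValueError(f"coords must be ({n}, 3)")
    d = squareform(pdist(coords))
    d_norm = np.exp(-d)
    iu = np.triu_indices(n, k=1)
    pair_ok = ~np.isnan(net.coherence[iu])
    y = logit(np.clip(net.coherence[iu][pair_ok], LOGIT_CLIP, 1 - LOGIT_CLIP))
    x = d_norm[iu][pair_ok]
    resid_mat = np.full((n, n), np.nan)
    if np.ptp(x) == 0:
        warnings.warn(
            "all inter-electrode distances identical; residualizing against the "
            "intercept only",
            stacklevel=2,
        )
        resid = y - y.mean()
    else:
        design = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
    rows, cols = iu[0][pair_ok], iu[1][pair_ok]
    resid_mat[rows, cols] = resid
    resid_mat[cols, rows] = resid
    net.residual = resid_mat
    net.dist_norm = d_norm
    return net


def node_strength(net: CoherenceNetwork, site: int, use: str = "residual") -> float:
    """Mean connectivity of ``site`` to every other unmasked electrode."""
    if not net.good[site]:
        raise ValueError(f"site {site} is masked (excluded channel)")
    mat = net.residual if use == "residual" else net.coherence
    if mat is None:
        raise ValueError("network has no residualized coherence; run residualize_distance")
    row = mat[site]
    others = net.good & (np.arange(row.size) != site)
    vals = row[others]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no unmasked neighbors")
    return float(vals.mean())


def power_connectivity_corr(
    t_values: np.ndarray, net: CoherenceNetwork, site: int, use: str = "residual"
) -> tuple[float, float]:
    """Correlate electrode t-statistics with their connectivity to the site.

    ``t_values`` is aligned with the network's electrode axis (NaN where an
    electrode has no statistic). Returns (Pearson r, Fisher z = atanh r).
    """
    if not net.good[site]:
        raise ValueError(f"site {site} is masked (excluded channel)")
    mat = net.residual if use == "residual" else net.coherence
    if mat is None:
        raise ValueError("network has no residualized coherence; run residualize_distance")
    t_values = np.asarray(t_values, float)
    conn = mat[site]
    ok = net.good & ~np.isnan(conn) & ~np.isnan(t_values)
    ok[site] = False
    if ok.sum() < 3:
        raise ValueError("need at least 3 recording electrodes with both values")
    x, y = conn[ok], t_values[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(pearsonr(x, y).statistic)
    return r, float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))


def site_level_correlates(
    site_values: np.ndarray, site_covariates: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation across stimulation sites (e.g. Fisher-z r values
    against normalized white-matter distance or node strength)."""
    x = np.asarray(site_values, float)
    y = np.asarray(site_covariates, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired site values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
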