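"""Stimulation-frequency x sense-frequency response matrices.

Row f of the matrix is computed from trials stimulated at f Hz only; column
g is the paired pre/post t-statistic on log power in the single 1-Hz sense
bin centered at g. The specificity score of an electrode is the mean of the
diagonal entries minus the mean of the off-diagonal entries, so a positive
score means stimulation preferentially drives power at its own frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectral import per_frequency_tstats

THETA_GRID = np.arange(3.0, 9.0)


def stim_sense_matrix(
    pre_powers: np.ndarray,
    post_powers: np.ndarray,
    trial_freqs: np.ndarray,
    freqs: np.ndarray = THETA_GRID,
) -> np.ndarray:
    """Per-electrode stim/sense matrices.

    ``pre_powers``/``post_powers`` are (n_channels, n_trials, n_sense_freqs)
    trial power stacks on the 1-Hz theta grid; ``trial_freqs`` gives each
    trial's burst frequency. Returns (n_channels, n_stim, n_sense) matrices
    with rows ordered like ``freqs``.
    """
    pre = np.asarray(pre_powers, float)
    post = np.asarray(post_powers, float)
    trial_freqs = np.asarray(trial_freqs, float)
    if pre.shape != post.shape or pre.ndim != 3:
        raise ValueError("power stacks must be matching (channels, trials, freqs) arrays")
    if pre.shape[2] != len(freqs):
        raise ValueError("sense-frequency axis does not match the requested grid")
    missing = [f for f in freqs if (trial_freqs == f).sum() < 2]
    if missing:
        raise ValueError(f"fewer than 2 trials at stimulation frequencies {missing}")
    n_ch = pre.shape[0]
    m = np.zeros((n_ch, len(freqs), len(freqs)))
    for i, f in enumerate(freqs):
        sel = trial_freqs == f
        for ch in range(n_ch):
            m[ch, i] = per_frequency_tstats(pre[ch, sel], post[ch, sel])
    return m


def specificity_score(matrix: np.ndarray) -> np.ndarray | float:
    """Diagonal-contrast score: mean(diagonal) - mean(off-diagonal).

    Accepts one (k, k) matrix or a stack (..., k, k); NaN entries make the
    matrix incomplete and raise.
    """
    m = np.asarray(matrix, float)
    if m.ndim < 2 or m.shape[-1] != m.shape[-2]:
        raise ValueError("expected a square stim/sense matrix")
    if np.isnan(m).any():
        raise ValueError("incomplete stim/sense matrix (NaN entries)")
    k = m.shape[-1]
    eye = np.eye(k, dtype=bool)
    diag = m[..., eye].mean(axis=-1)
    off = m[..., ~eye].mean(axis=-1)
    score = diag - off
    return float(score) if score.ndim == 0 else score


def matrix_frame(mean_matrix: np.ndarray, freqs: np.ndarray = THETA_GRID) -> pd.DataFrame:
    """Across-electrode mean matrix as a labeled table (rows = stimulation Hz)."""
    labels = [f"{f:g}" for f in freqs]
    return pd.DataFrame(mean_matrix, index=pd.Index(labels, name="stim_Hz"), columns=labels)
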