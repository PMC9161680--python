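"""Hierarchical and permutation inference for stimulation-response statistics.

Electrode-level statistics are correlated within subjects and sessions, so
population effects are estimated with linear mixed-effects models (LMMs)
specifying sessions nested within subjects as random effects. Significance
of a coefficient uses the Wald z (estimate / SE); significance of a fixed
covariate with random slopes uses the likelihood ratio between nested
models refit by full maximum likelihood against a chi-square reference.

The during/post power coupling uses a circular-shift permutation null: the
Pearson correlation of x with every nonzero circular shift of y, and with
every circular shift of the reversed y, preserving serial dependence within
each vector while destroying their alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054


@dataclass
class LmmResult:
    """Fixed-effect table plus fit metadata from a mixed model."""

    fixed_effects: pd.DataFrame  # estimate, se, z, p, ci_low, ci_high per coefficient
    llf: float
    grouping: str
    re_variances: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    fallback: bool = False
    contrasts: pd.DataFrame | None = None

    @property
    def intercept_z(self) -> float:
        return float(self.fixed_effects.loc["Intercept", "z"])

    @property
    def intercept_p(self) -> float:
        return float(self.fixed_effects.loc["Intercept", "p"])


def _prepare(values, subjects, sessions) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "subject": np.asarray(subjects),
        }
    )
    df["session"] = np.asarray(sessions) if sessions is not None else df["subject"]
    if df["value"].isna().any():
        df = df.dropna(subset=["value"]).reset_index(drop=True)
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    return df


def _sessions_identifiable(df: pd.DataFrame) -> bool:
    return (df.groupby("subject")["session"].nunique() > 1).any()


def _fe_table(result, names: list[str]) -> pd.DataFrame:
    est = np.asarray(result.fe_params, float)
    se = np.asarray(result.bse_fe, float)
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
        },
        index=names,
    )


def _fit_mixed(formula, df, re_formula, vc_formula, reml=True):
    import statsmodels.formula.api as smf

    model = smf.mixedlm(
        formula, df, groups=df["subject"], re_formula=re_formula, vc_formula=vc_formula
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=reml)


def _fit_mixed_ml_best(formula, df, re_formula, vc_formula):
    """Full-ML fit taking the best finite log-likelihood over optimizers.

    The default optimizer can stop short of the ML optimum (or report an
    infinite likelihood on degenerate fits); a likelihood-ratio statistic
    needs both models at their true optima, so each model is also fit with
    Powell and the better finite solution kept.
    """
    import statsmodels.formula.api as smf

    model = smf.mixedlm(
        formula, df, groups=df["subject"], re_formula=re_formula, vc_formula=vc_formula
    )
    best = None
    for method in (None, "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=False) if method is None else model.fit(
                    reml=False, method=method
                )
        except (np.linalg.LinAlgError, ValueError):
            continue
        llf = float(fit.llf)
        if not np.isfinite(llf):
            continue
        if best is None or llf > float(best.llf):
            best = fit
    if best is None:
        raise ValueError("mixed-model likelihood optimization failed for all optimizers")
    return best


def _usable(result) -> bool:
    """A fit is usable when its fixed-effect standard errors are finite.

    statsmodels reports ``converged=False`` whenever a variance component sits
    on the boundary, which is routine and leaves the estimates valid; a
    genuinely singular fit shows up as NaN standard errors.
    """
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore")
        bse = np.asarray(result.bse_fe, float)
    return bool(np.isfinite(bse).all())


def fit_intercept_lmm(values, subjects, sessions=None) -> LmmResult:
    """Intercept-only LMM: value = mu + u_subject + u_session(subject) + noise.

    Returns the Wald test of mu = 0. If the nested fit is singular or fails
    to converge, the model falls back to a subject-only random intercept and
    flags the fallback in the result.
    """
    df = _prepare(values, subjects, sessions)
    use_sessions = _sessions_identifiable(df)
    vc = {"session": "0 + C(session)"} if use_sessions else None
    result = _fit_mixed("value ~ 1", df, "1", vc, reml=True)
    fallback = False
    if use_sessions and not _usable(result):
        warnings.warn(
            "nested session/subject fit is singular; falling back to a subject-only "
            "random intercept",
            stacklevel=2,
        )
        result = _fit_mixed("value ~ 1", df, "1", None, reml=True)
        fallback = True
        use_sessions = False
    re_var = {"subject": float(np.asarray(result.cov_re)[0, 0])}
    if use_sessions:
        re_var["session"] = float(result.vcomp[0])
    re_var["residual"] = float(result.scale)
    return LmmResult(
        fixed_effects=_fe_table(result, list(result.fe_params.index)),
        llf=float(result.llf),
        grouping="sessions nested in subjects" if use_sessions else "subjects only",
        re_variances=re_var,
        converged=bool(result.converged),
        fallback=fallback,
    )


def fit_categorical_lmm(values, factor, subjects, sessions=None, holm: bool = False) -> LmmResult:
    """LMM with a categorical fixed effect (stimulation frequency) and all
    pairwise Wald contrasts between factor levels.

    Contrasts are reported unadjusted by default; ``holm=True`` adds
    Holm-corrected p-values.
    """
    df = _prepare(values, subjects, sessions)
    df["factor"] = np.asarray(factor)[: len(df)]
    levels = sorted(df["factor"].unique())
    if len(levels) < 2:
        raise ValueError("categorical LMM needs at least 2 factor levels")
    small = [lv for lv in levels if (df["factor"] == lv).sum() < 2]
    if small:
        raise ValueError(f"factor levels with fewer than 2 observations: {small}")
    vc = {"session": "0 + C(session)"} if _sessions_identifiable(df) else None
    result = _fit_mixed("value ~ C(factor)", df, "1", vc, reml=True)
    if vc is not None and not _usable(result):
        warnings.warn("nested fit singular; using subject-only random intercept", stacklevel=2)
        vc = None
        result = _fit_mixed("value ~ C(factor)", df, "1", None, reml=True)
    names = list(result.fe_params.index)
    fe = _fe_table(result, names)
    k = len(names)
    cov = np.asarray(result.cov_params())[:k, :k]
    est = np.asarray(result.fe_params, float)

    def level_vec(lv):
        v = np.zeros(k)
        v[0] = 1.0
        name = f"C(factor)[T.{lv}]"
        if name in names:
            v[names.index(name)] = 1.0
        return v

    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            L = level_vec(levels[j]) - level_vec(levels[i])
            delta = float(L @ est)
            se = float(np.sqrt(L @ cov @ L))
            z = delta / se
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "estimate": delta,
                    "se": se,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)),
                }
            )
    contrasts = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        contrasts["p_holm"] = multipletests(contrasts["p"], method="holm")[1]
    return LmmResult(
        fixed_effects=fe,
        llf=float(result.llf),
        grouping="sessions nested in subjects" if vc else "subjects only",
        converged=bool(result.converged),
        contrasts=contrasts,
    )


@dataclass
class LrtResult:
    chi2: float
    df: int
    p_value: float
    slope: float
    converged: bool = True


def lrt_fixed_effect(values, covariate, subjects, sessions=None) -> LrtResult:
    """Likelihood-ratio test of a fixed covariate with random slopes.

    Full model: fixed slope, subject random intercept + random slope (with
    covariance), and — when subjects have multiple sessions — session-level
    random intercepts and slopes. Reduced model drops the fixed slope and
    all random slopes. Both are refit by full maximum likelihood; the LRT
    statistic is referred to chi-square with df equal to the parameter-count
    difference (4 with session components, 3 without).
    """
    df = _prepare(values, subjects, sessions)
    x = np.asarray(covariate, float)[: len(df)]
    df["x"] = x
    if np.ptp(df["x"].to_numpy()) == 0:
        return LrtResult(chi2=0.0, df=4, p_value=1.0, slope=0.0)
    use_sessions = _sessions_identifiable(df)
    if use_sessions:
        vc_full = {"session": "0 + C(session)", "session_slope": "0 + C(session):x"}
        vc_red = {"session": "0 + C(session)"}
        k_diff = 4  # fixed slope + subject slope var + subject cov + session slope var
    else:
        vc_full, vc_red = None, None
        k_diff = 3  # fixed slope + subject slope var + subject cov
    full = _fit_mixed_ml_best("value ~ x", df, "1 + x", vc_full)
    if use_sessions and not _usable(full):
        warnings.warn(
            "session-level random slopes unidentifiable; dropping session components",
            stacklevel=2,
        )
        vc_full, vc_red, k_diff = None, None, 3
        full = _fit_mixed_ml_best("value ~ x", df, "1 + x", None)
    reduced = _fit_mixed_ml_best("value ~ 1", df, "1", vc_red)
    lr = max(0.0, 2.0 * (float(full.llf) - float(reduced.llf)))
    p = float(stats.chi2.sf(lr, k_diff)) if lr > 0 else 1.0
    return LrtResult(
        chi2=lr,
        df=k_diff,
        p_value=p,
        slope=float(full.fe_params["x"]),
        converged=bool(full.converged and reduced.converged),
    )


@dataclass
class PermutationNull:
    """Observed correlation, the circular-shift null, and its one-sided p."""

    observed: float
    null: np.ndarray
    p_value: float


def circular_shift_permutation(x: np.ndarray, y: np.ndarray) -> PermutationNull:
    """Circular-shift permutation test of the Pearson correlation.

    The null comprises the correlations of x with every nonzero circular
    shift of y ((n-1) values) and with every circular shift of the reversed
    y (n values), 2n - 1 in total; serial structure within each vector is
    preserved. The one-sided p for positive association uses the add-one
    convention, so p is never zero and is exact under exchangeability.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    shifted = [np.roll(y, k) for k in range(1, n)]
    mirrored = [np.roll(y[::-1], k) for k in range(n)]
    stack = np.stack(shifted + mirrored)  # (2n-1, n)
    xc = x - x.mean()
    sc = stack - stack.mean(axis=1, keepdims=True)
    null = (sc @ xc) / (np.linalg.norm(sc, axis=1) * np.linalg.norm(xc))
    observed = float(np.dot(y - y.mean(), xc) / (np.linalg.norm(y - y.mean()) * np.linalg.norm(xc)))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + null.size)
    return PermutationNull(observed=observed, null=null, p_value=float(p))


def session_quartile_anova(
    trial_times: np.ndarray,
    values: np.ndarray,
    subjects: np.ndarray,
    n_bins: int = 4,
) -> tuple[float, float, pd.DataFrame]:
    """Repeated-measures ANOVA of induced power over session quartiles.

    Each subject's trials are binned into ``n_bins`` equal spans of the
    session (quartiles for a 24-min session: 6 min each); the within-subject
    bin means enter a one-way repeated-measures ANOVA over the bin factor.
    Subjects missing any bin are dropped with a warning. Returns (F, p,
    subject x bin mean table).
    """
    t = np.asarray(trial_times, float)
    v = np.asarray(values, float)
    s = np.asarray(subjects)
    table = {}
    for subj in pd.unique(s):
        sel = s == subj
        ts, vs = t[sel], v[sel]
        span = ts.max() - ts.min()
        if span == 0:
            warnings.warn(f"subject {subj!r} has zero session span; dropped", stacklevel=2)
            continue
        bins = np.minimum((n_bins * (ts - ts.min()) / span).astype(int), n_bins - 1)
        means = [vs[bins == b].mean() if (bins == b).any() else np.nan for b in range(n_bins)]
        if np.isnan(means).any():
            warnings.warn(f"subject {subj!r} missing a session quartile; dropped", stacklevel=2)
            continue
        table[subj] = means
    if len(table) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 complete subjects")
    m = pd.DataFrame(table).T  # subjects x bins
    arr = m.to_numpy()
    n_s, k = arr.shape
    grand = arr.mean()
    ss_effect = n_s * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_error = ss_total - ss_effect - ss_subject
    if ss_effect <= 0:
        return 0.0, 1.0, m
    df_eff = k - 1
    df_err = (n_s - 1) * (k - 1)
    f_stat = (ss_effect / df_eff) / (ss_error / df_err)
    p = float(stats.f.sf(f_stat, df_eff, df_err))
    return float(f_stat), p, m
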