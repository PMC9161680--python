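"""End-to-end orchestration: simulate -> segment -> power -> timecourse ->
specificity -> connectivity -> inference, as a configured, logged run.

A run is driven by a :class:`RunConfig` (YAML-serializable). Outputs land in
a run directory as CSV/JSON tables plus a manifest recording the config,
package versions, seeds, and output hashes, so a rerun from the serialized
config reproduces deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, connectivity, inference, simulate, specificity, spectral, timecourse


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "tbs_run"
    # synthetic cohort
    n_subjects: int = 2
    n_sessions: int = 2
    n_channels: int = 12
    fs: float = 500.0
    trials_per_freq: int = 5
    coupling_response_corr: float = 0.8
    gain_scale: float = 3.0
    decay_tau: float = 0.5
    noise_sd: float = 1.0
    baseline_periods: int = 10
    # stage toggles
    run_power: bool = True
    run_timecourse: bool = True
    run_specificity: bool = True
    run_connectivity: bool = True
    run_inference: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = [f"thetaburst {__version__} run, seed {config.seed}"]

    template = simulate.SimulationConfig(
        n_channels=config.n_channels,
        fs=config.fs,
        decay_tau=config.decay_tau,
        noise_sd=config.noise_sd,
    )
    sessions = simulate.coupled_cohort(
        config.n_subjects,
        template,
        config.coupling_response_corr,
        seed=config.seed,
        n_sessions=config.n_sessions,
        schedule_kwargs={"trials_per_freq": config.trials_per_freq},
        gain_scale=config.gain_scale,
        baseline_periods=config.baseline_periods,
    )
    log.append(f"simulated {len(sessions)} sessions across {config.n_subjects} subjects")

    stats_rows, sense_stacks, scores = [], [], []
    coupling_rows, conn_rows = [], []
    trial_rows = []
    decay_frames = []
    lmm_values, lmm_subject, lmm_session, lmm_conn = [], [], [], []
    freq_values, freq_factor, freq_subject, freq_session = [], [], [], []

    for sess in sessions:
        rec, sched = sess.recording, sess.schedule
        if not config.run_power:
            continue
        stats = spectral.electrode_stats(rec, sched, band="theta")
        counts = spectral.classify_responders(stats)
        good = rec.good_indices()
        t_by_channel = np.full(rec.n_channels, np.nan)
        for st, ch in zip(stats, good):
            t_by_channel[ch] = st.band_t
        frame = spectral.stats_frame(stats)
        frame.insert(0, "session", sess.session)
        frame.insert(0, "subject", sess.subject)
        stats_rows.append(frame)

        for st in stats:
            lmm_values.append(st.band_t)
            lmm_subject.append(sess.subject)
            lmm_session.append(sess.session)
            for f, t in st.stim_t.items():
                freq_values.append(t)
                freq_factor.append(f)
                freq_subject.append(sess.subject)
                freq_session.append(sess.session)

        responsive = [i for i, st in enumerate(stats) if st.responder == "responsive"]
        if config.run_specificity and responsive:
            freqs, pre_p, post_p = spectral.trial_band_powers(
                rec, sched, 3.0, 8.0, analysis_fs=50.0, tbw=spectral.SENSE_TBW
            )
            chans = good[responsive]
            mats = specificity.stim_sense_matrix(
                pre_p[chans], post_p[chans], sched.trial_freqs
            )
            sense_stacks.append(mats)
            sc = specificity.specificity_score(mats)
            for ch, s in zip(chans, np.atleast_1d(sc)):
                scores.append(
                    {
                        "subject": sess.subject,
                        "session": sess.session,
                        "label": rec.channels[ch].label,
                        "specificity": float(s),
                    }
                )

        if config.run_timecourse and responsive:
            sub = {rec.channels[good[i]].label: None for i in responsive}
            tcs = {}
            all_tcs = timecourse.electrode_timecourses(rec, sched)
            for lab in sub:
                tcs[lab] = all_tcs[lab]
            df = timecourse.decay_summary(tcs)
            df.insert(0, "session", sess.session)
            df.insert(0, "subject", sess.subject)
            decay_frames.append(df)
            d_t, p_t, _ = timecourse.during_tstats(rec, sched)
            try:
                r, p = timecourse.during_post_coupling(d_t, p_t)
                coupling_rows.append(
                    {"subject": sess.subject, "session": sess.session, "r": r, "p": p}
                )
            except ValueError as err:
                log.append(f"session {sess.session}: coupling skipped ({err})")

        if config.run_connectivity:
            net = connectivity.baseline_coherence(rec, sess.baseline)
            net = connectivity.residualize_distance(net, rec.coords())
            site = sess.stim_channel
            row = {
                "subject": sess.subject,
                "session": sess.session,
                "site": rec.channels[site].label,
                "node_strength": connectivity.node_strength(net, site),
            }
            try:
                r, fz = connectivity.power_connectivity_corr(t_by_channel, net, site)
                row.update({"power_conn_r": r, "power_conn_fisher_z": fz})
            except ValueError as err:
                log.append(f"session {sess.session}: power-connectivity skipped ({err})")
            conn_rows.append(row)
            for st, ch in zip(stats, good):
                lmm_conn.append(net.residual[site, ch])

        # per-trial induced theta power for the session-quartile analysis
        freqs, pre_p, post_p = spectral.trial_band_powers(rec, sched, 3.0, 8.0, analysis_fs=50.0)
        use = good[responsive] if responsive else good
        induced = (np.log(post_p[use]) - np.log(pre_p[use])).mean(axis=(0, 2))
        for tr in range(sched.n_trials):
            trial_rows.append(
                {
                    "subject": sess.subject,
                    "session": sess.session,
                    "trial_time_s": sched.onsets[tr] / sched.fs,
                    "induced_power": induced[tr],
                }
            )

    outputs: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        outputs[name] = p

    if stats_rows:
        all_stats = pd.concat(stats_rows, ignore_index=True)
        _write(all_stats, "electrode_stats.csv")
        counts = {
            "responsive": int((all_stats["responder"] == "responsive").sum()),
            "negative": int((all_stats["responder"] == "negative").sum()),
            "none": int((all_stats["responder"] == "none").sum()),
            "total": int(len(all_stats)),
        }
        counts["prop_responsive"] = counts["responsive"] / counts["total"]
        (out / "responder_counts.json").write_text(json.dumps(counts, indent=2))
        outputs["responder_counts.json"] = out / "responder_counts.json"
    if sense_stacks:
        mean_mat = np.concatenate(sense_stacks).mean(axis=0)
        mdf = specificity.matrix_frame(mean_mat)
        mdf.to_csv(out / "stim_sense_mean.csv")
        outputs["stim_sense_mean.csv"] = out / "stim_sense_mean.csv"
        _write(pd.DataFrame(scores), "specificity_scores.csv")
    if decay_frames:
        _write(pd.concat(decay_frames, ignore_index=True), "decay_summary.csv")
    if coupling_rows:
        _write(pd.DataFrame(coupling_rows), "during_post_coupling.csv")
    if conn_rows:
        _write(pd.DataFrame(conn_rows), "connectivity_sites.csv")
    if trial_rows:
        _write(pd.DataFrame(trial_rows), "trial_induced_power.csv")

    if config.run_inference and lmm_values:
        summary: dict = {}
        try:
            res = inference.fit_intercept_lmm(lmm_values, lmm_subject, lmm_session)
            summary["intercept_lmm"] = {
                "estimate": float(res.fixed_effects.loc["Intercept", "estimate"]),
                "z": res.intercept_z,
                "p": res.intercept_p,
                "grouping": res.grouping,
            }
        except ValueError as err:
            log.append(f"intercept LMM skipped ({err})")
        try:
            res = inference.fit_categorical_lmm(
                freq_values, freq_factor, freq_subject, freq_session
            )
            summary["frequency_lmm"] = {
                "levels": sorted(set(freq_factor)),
                "n_contrasts": int(len(res.contrasts)),
                "min_contrast_p": float(res.contrasts["p"].min()),
            }
        except ValueError as err:
            log.append(f"frequency LMM skipped ({err})")
        if config.run_connectivity and lmm_conn:
            try:
                lrt = inference.lrt_fixed_effect(lmm_values, lmm_conn, lmm_subject, lmm_session)
                summary["connectivity_lrt"] = {
                    "chi2": lrt.chi2,
                    "df": lrt.df,
                    "p": lrt.p_value,
                    "slope": lrt.slope,
                }
            except ValueError as err:
                log.append(f"connectivity LRT skipped ({err})")
        if trial_rows:
            tdf = pd.DataFrame(trial_rows)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    f_stat, p, _ = inference.session_quartile_anova(
                        tdf["trial_time_s"], tdf["induced_power"], tdf["subject"]
                    )
                    summary["session_quartile_anova"] = {"F": f_stat, "p": p}
                except ValueError as err:
                    log.append(f"quartile ANOVA skipped ({err})")
        (out / "inference.json").write_text(json.dumps(summary, indent=2))
        outputs["inference.json"] = out / "inference.json"

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def make_report(run_dir: str | Path) -> Path:
    """Summarize a completed run into a plain-text report of figure-analog tables."""
    run_dir = Path(run_dir)
    lines = ["# thetaburst run report", ""]
    warnings_list = []

    def section(title: str) -> None:
        lines.extend(["", f"## {title}", ""])

    counts_path = run_dir / "responder_counts.json"
    if counts_path.exists():
        counts = json.loads(counts_path.read_text())
        section("Responder counts")
        lines.append(
            f"responsive {counts['responsive']} / {counts['total']} "
            f"({100 * counts['prop_responsive']:.1f}%), negative {counts['negative']}"
        )
    else:
        warnings_list.append("responder counts missing")

    stats_path = run_dir / "electrode_stats.csv"
    if stats_path.exists():
        df = pd.read_csv(stats_path)
        section("Session t-statistic distributions")
        g = df.groupby(["subject", "session"])["band_t"].agg(["mean", "std", "count"])
        lines.append(g.round(3).to_string())
    else:
        warnings_list.append("electrode stats missing")

    mat_path = run_dir / "stim_sense_mean.csv"
    if mat_path.exists():
        section("Mean stimulation/sense matrix (t)")
        lines.append(pd.read_csv(mat_path, index_col=0).round(2).to_string())
        sc = pd.read_csv(run_dir / "specificity_scores.csv")
        lines.append("")
        lines.append(
            f"specificity score over {len(sc)} responsive electrodes: "
            f"mean {sc['specificity'].mean():.3f}"
        )
    else:
        warnings_list.append("no responsive electrodes; specificity section omitted")

    decay_path = run_dir / "decay_summary.csv"
    if decay_path.exists():
        df = pd.read_csv(decay_path)
        section("Theta decay times")
        ok = df[df["status"] == "ok"]["decay_time_s"]
        lines.append(
            f"n ok = {len(ok)}, mean decay {ok.mean():.3f} s; "
            f"censored {int((df['status'] == 'censored').sum())}, "
            f"excluded {int((df['status'] == 'excluded').sum())}"
        )
        if len(ok):
            hist, edges = np.histogram(ok, bins=np.arange(0, 1.1, 0.1))
            lines.append("decay histogram (0.1 s bins): " + " ".join(str(h) for h in hist))

    coup_path = run_dir / "during_post_coupling.csv"
    if coup_path.exists():
        df = pd.read_csv(coup_path)
        section("During/post power coupling")
        lines.append(
            f"mean r = {df['r'].mean():.3f} +/- {df['r'].std(ddof=0):.3f} SD over "
            f"{len(df)} sessions; significant (p < 0.05) in {(df['p'] < 0.05).sum()}"
        )

    conn_path = run_dir / "connectivity_sites.csv"
    if conn_path.exists():
        section("Power-connectivity by stimulation site")
        lines.append(pd.read_csv(conn_path).round(3).to_string(index=False))

    inf_path = run_dir / "inference.json"
    if inf_path.exists():
        section("Inference summaries")
        lines.append(json.dumps(json.loads(inf_path.read_text()), indent=2))
    else:
        warnings_list.append("inference summaries missing")

    if warnings_list:
        section("Warnings")
        lines.extend(f"- {w}" for w in warnings_list)

    report = run_dir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
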