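# thetaburst

Analysis of how intracranial theta-burst stimulation (TBS) entrains
frequency-specific oscillations in human iEEG, packaged as a reusable,
tested pipeline with a synthetic LFP generator for ground-truth validation.

TBS delivers short bursts of 100–200 Hz pulses repeated at a theta-range
burst frequency (3–8 Hz). The scientific questions this package addresses,
for electrophysiologists working with stimulation + recording datasets:

- Does stimulation increase theta power at non-stimulated electrodes?
  Per electrode, multitaper PSDs in 1-s pre/post windows yield a paired
  t-statistic on band-mean log power; t > 2 defines "responsive".
- Is the induced rhythm frequency-specific? A 6×6 stimulation × sense
  frequency matrix of per-1-Hz-bin t-statistics; the specificity score is
  mean(diagonal) − mean(off-diagonal).
- How long does the entrained rhythm persist? Convolutional time–frequency
  power (2-cycle DPSS windows), trial-averaged and z-scored to the 0–500 ms
  pre-onset baseline; the **theta decay time** is the interval from the last
  pulse until z < 1.
- Is during-stimulation power physiologic? Pearson correlation of during-
  vs post-stimulation t values with a circular-shift permutation null that
  preserves serial dependence.
- Does baseline connectivity predict where power is induced? 5–13 Hz
  multitaper coherence networks C_xy = |S_xy| / √(S_xx S_yy), logit-
  transformed and residualized on normalized inter-electrode distance
  e^(−d); a mixed-model likelihood-ratio test (random intercepts + slopes)
  quantifies the connectivity → induced-power relationship.
- Population inference uses hierarchical linear mixed models with sessions
  nested in subjects and Wald z = β̂ / SE.

## Worked example

Run the full synthetic pipeline (2 subjects × 2 sessions, 8 channels,
24 trials per session, coupling–response correlation 0.8) and report it:

```bash
tbs run --config run.yaml     # or: python -m thetaburst.cli run --config run.yaml
tbs report tbs_run
```

with `run.yaml`:

```yaml
seed: 1
out_dir: tbs_run
n_subjects: 2
n_sessions: 2
n_channels: 8
trials_per_freq: 4
gain_scale: 4.0
```

The report (`tbs_run/report.txt`) contains, among other tables:

```
## Responder counts

responsive 28 / 28 (100.0%), negative 0

## Mean stimulation/sense matrix (t)

            3      4     5      6     7      8
stim_Hz
3        7.56   3.39  0.28   0.21  0.27  -0.16
4        4.55  10.32  5.91   0.25  0.04   0.43
5       -0.09   3.46  9.42   5.21  0.94   0.49
6       -0.47   1.02  5.09  11.90  4.54   0.54
7       -0.59  -0.92  0.37   5.38  9.68   5.64
8       -0.63  -0.93 -0.42   0.94  5.75  12.36
```

Every row of the stimulation/sense matrix peaks on its own diagonal — the
synthetic responses are frequency-locked and the pipeline recovers that.
`tbs_run/inference.json` holds the hierarchical model summaries; for this
configuration the connectivity likelihood-ratio test gives
χ²(4) = 17.6, p = 0.0015 with a positive coherence slope (β = 4.74), i.e.
electrodes more coherent with the stimulation site (independent of
distance) show larger induced theta power, as constructed.

The same stages are importable as a library (`thetaburst.spectral`,
`.timecourse`, `.specificity`, `.connectivity`, `.inference`,
`.simulate`, `.io`) and operate on `Recording` + `StimSchedule` objects or
plain arrays; see `docs/methods.md` for the underlying models.

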