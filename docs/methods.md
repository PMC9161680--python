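# Methods

This note documents the models, estimators, and design choices behind the
package, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite does not itself compute.

## Stimulation paradigm and data model

A stimulation *trial* is 5 bursts of 5 pulses at 100–200 Hz; bursts repeat
at the trial's burst frequency f ∈ {3,…,8} Hz, so the inter-burst interval
is round(1000/f) ms ∈ {333, 250, 200, 167, 143, 125}. A *session* delivers
60 trials per frequency (360 total), randomly interleaved, spaced 3 s apart
with ±200 ms uniform jitter. Sample indices are 0-based; all windows are
half-open `[start, stop)`; an event's `offset` is the first sample after
the last pulse. Stimulated channels are flagged and excluded from every
per-electrode power analysis; quality-excluded channels (non-physiologic,
ictal, seizure-onset zone) are excluded everywhere, including coherence
networks, whereas stimulated channels remain in the networks because their
baseline (pre-task) signal is stimulation-free and they anchor the
site-level connectivity analyses.

## Spectral power and responder statistics

Power in the fixed −1000…0 ms (pre) and 0…+1000 ms-after-offset (post)
windows is estimated with Slepian (DPSS) multitapers: time–bandwidth
product NW = 3, unweighted average over tapers with eigenvalue
(spectral concentration) ≥ 0.90, one-sided density 2|X|²/fs for unit-energy
tapers. Theta analyses run at 50 Hz; alpha/beta at 100 Hz; gamma/HFB at
500 Hz, where the windows additionally exclude the 100 ms flanking the
stimulation interval (0.9 s effective) to keep pulse artifact out, and
electrodes with theta t > 5 are dropped as likely corrupted.

The electrode statistic is a paired t over trials on band-mean natural-log
power (post vs pre); t > 2 labels an electrode responsive, t < −2 negative.
Natural log is immaterial to t (scale-free) and fixed for reproducibility.
If all paired differences are identical the t is ±∞ by sign (limit case),
0 for exact ties at zero.

**Frequency-resolved statistics use a narrower taper family.** On a 1-s
window, NW = 3 concentrates energy over ±3 Hz: a pure tone spreads almost
flat across the whole 3–8 Hz band, so per-1-Hz-bin statistics computed with
that family cannot attribute a response to its bin — against a 1/f
background the log-ratio then tilts toward the high bins regardless of the
true frequency. Band-level t keeps NW = 3; the stimulation/sense matrices
use a single NW = 1 Slepian whose half-bandwidth equals the 1-Hz bin
spacing. With that family a frequency-locked synthetic session recovers a
perfect diagonal.

## Stimulation/sense matrices and specificity

Entry (f, g) is the paired pre/post t at sense bin g over the trials
stimulated at f. The specificity score is mean(diagonal) −
mean(off-diagonal); it is invariant to adding a constant to the matrix and
scales linearly with it. Matrices are computed on the responsive subset by
default (the threshold selects electrodes for characterization, not for
inference); cohort-level inference on scores goes through the intercept-only
mixed model.

## Theta timecourse and decay

Time-resolved power comes from MNE's multitaper convolution with 2-cycle
windows and time–bandwidth 2 (one taper), so stimulation-interval energy
can smear at most one window into the flanking data. Per electrode the
pipeline averages power over 3–8 Hz, then over trials, then z-scores the
averaged trace against the mean/SD of its own −500…0 ms baseline (the
"within 1 SD" decay criterion refers to the trial-averaged signal; the
baseline SD of a single-trial trace would be far larger). The decay time is
the first sample ≥ the last pulse at which z < 1, at sample resolution and
capped at a 1-s post window: traces that never return are *censored* and
omitted from summaries; electrodes whose z never reaches 2 are *excluded*.

For an injected amplitude decay exp(−t/τ) the power envelope decays as
exp(−2t/τ), so a trace starting at z₀ crosses 1 at (τ/2)·ln z₀. The
estimator is validated against this closed form at high SNR (z₀ ≫ 1),
where the crossing is deterministic; at physiologic SNR (z₀ ≈ 2–8) the
first-crossing time carries jitter of the order of the convolution window,
because the z trace's noise SD is 1 by construction while the trace slope
near the crossing is ≈ 2/τ. This jitter is a property of the metric, not
of the implementation.

During-stimulation statistics use matched non-sliding windows (pre window
of the same duration as the stimulation interval, ending at onset), so no
taper overlaps both intervals. The during/post coupling is the Pearson
correlation of the two electrode × stimulation-frequency t matrices,
flattened; its p-value comes from the circular-shift permutation null.

## Circular-shift permutation test

For vectors of length n the null comprises the correlations of x with all
n−1 nonzero circular shifts of y plus all n shifts of the reversed y
(2n − 1 values): shifts preserve the serial dependence within each vector
while destroying their alignment, correcting for the non-independence of
t-statistics across electrodes and frequencies. Shifting only y avoids
duplicating correlations that shifting x would reproduce. The one-sided p
uses the add-one convention, p = (1 + #{null ≥ observed})/(1 + 2n − 1),
which is exact under exchangeability and never zero.

## Coherence networks and distance residualization

Coherence is the normalized cross-spectral density magnitude,
C_xy(f) = |S_xy| / √(S_xx S_yy), estimated with NW = 4 multitapers (at most
8, eigenvalue ≥ 0.9) on sequential 1-s windows cut from 10-s baseline
periods; at least 100 windows are required. Cross- and auto-spectra are
averaged over all windows and tapers *before* normalization, then C is
averaged over 5–13 Hz. For y = a·x + independent noise this estimator
converges to √(ρ/(1+ρ)) with ρ the per-frequency power SNR, and for
independent channels it sits at a positive bias floor that shrinks as the
window × taper count grows — both properties are exercised in the tests.

Distances enter as d' = e^(−d) (d in mm; d = 0 ↦ 1). Coherence is clipped
to [1e−6, 1−1e−6], logit-transformed, and regressed on d' by OLS over all
unmasked pairs; the residuals are the distance-independent connectivity.
If all pairs are equidistant the regression degenerates and the residuals
fall back to centered logit coherence with a warning. Node strength is the
mean of a site's row (residualized by default). Site-level analyses
correlate per-site Fisher-z power–connectivity r values with external
covariates (e.g. precomputed white-matter proximity e^(−d)); extraction of
such covariates from imaging is out of scope — they enter as scalars.

## Hierarchical inference

Electrode statistics are modeled as value = μ + u_subject + u_session(subject) + ε
with Gaussian components (statsmodels MixedLM; REML for estimation). The
Wald z is β̂/SE with a normal reference; 95% CI = β̂ ± 1.96·SE. If the
nested fit is singular (non-finite SEs) the model falls back to a
subject-only random intercept and says so. statsmodels flags
`converged=False` whenever a variance sits on its boundary; estimates
remain valid there, so usability is judged by finite SEs instead.

Stimulation frequency enters as a treatment-coded categorical fixed effect;
all 15 pairwise contrasts are Wald tests on the fixed-effect covariance,
reported unadjusted (Holm optionally), since the thresholding conventions
upstream are for subset selection rather than inference.

The connectivity effect is tested by a likelihood ratio between full-ML
fits: the full model carries the fixed slope, subject random intercept +
random slope (with covariance), and — when subjects have multiple
sessions — session-level random intercepts and slopes; the reduced model
drops the fixed slope and all random slopes. The parameter-count difference
is 4 (3 without session components) and the statistic is referred to
χ² with that df. Because variance parameters sit on the boundary under the
null, this reference is conservative (the exact null is a chi-square
mixture); the plain-χ² convention is retained and the conservatism is
visible in the null-calibration tests. Each model is fit with the default
optimizer and with Powell, keeping the best finite log-likelihood — the
default optimizer alone can stop short of the optimum and corrupt the
ratio in either direction.

Session-course analysis bins each session into quartiles (6 min of a
24-min session), takes within-subject quartile means, and runs a one-way
repeated-measures ANOVA implemented from sums of squares (so that the
degenerate all-equal case returns F = 0, p = 1, where a generic
implementation divides 0/0); it is checked against statsmodels' AnovaRM.

## Synthetic LFP generator

Background is 1/f^α noise (α = 1 by default) made by spectral shaping of
white Gaussian noise, unit variance per channel, at fs = 500 Hz by default.
Shared latent pink sources mixed through a channels × sources gain matrix
induce inter-channel coherence: with one source of weight c_i on channel i
and unit independent noise, the model coherence is
c_i c_j / √((1+c_i²)(1+c_j²)).

The evoked response is a sinusoid at the trial's burst frequency, phase 0
at onset (making trial-averaged timecourses deterministic in expectation),
ramping linearly over the first burst period (avoiding a spectral step the
analysis would misread), constant through the stimulation interval, and
decaying as exp(−t/τ) after offset (τ = 0.5 s default, matching the
half-second persistence scale the analysis targets). Per-channel amplitude
is the channel's `response_gain`. An optional pulse-train artifact places
biphasic spikes at the exact pulse times, strictly within [onset, offset),
on designated channels only. Everything injected is recorded in a
`GroundTruth` object.

`coupled_cohort` builds multi-subject cohorts in which each subject has a
latent "stimulation-site" source with per-channel couplings c_i ~ U(0.1, 1)
and per-session evoked gains whose standardized values correlate with the
standardized couplings at a requested ρ. Gains are scaled by each channel's
background SD √(noise_sd² + c_i²): without this, high-coupling channels
would have systematically smaller log-power responses at equal amplitude
and ρ = 0 would not be a true null for the power–connectivity analysis.
Subjects default to 2 sessions (matching the ~2 stimulation targets per
subject the paradigm uses), which also identifies the session-level
variance components of the mixed models.

What the generator does *not* emulate: non-sinusoidal and phase-drifting
oscillations, evoked potentials, non-stationary background (the 1/f process
is stationary apart from the injected responses), epileptiform transients,
line noise, and frequency-dependent coherence structure. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to every pathology of clinical iEEG.

## Problem sizes used by the validation suite

The acceptance-style tests run at desk scale, chosen as the smallest sizes
at which each property is statistically decidable: specificity recovery on
one 360-trial, 36-channel session at amplitude SNR 5; decay accuracy over
50 replicates × τ ∈ {0.2, 0.5, 1.0} s with 15 trials each; null calibration
over 500 gain-zero electrodes (60 trials each), 300 permutation draws of
length-60 vectors, and 100 values-level cohorts; connectivity recovery on
10-subject, 2-session, 12-channel cohorts with 30 trials per session, 50
replicates for the null arm. The null cohorts use noise_sd = 2 (baseline
coherences ≲ 0.2, typical of non-adjacent iEEG pairs); at much stronger
shared sources, correlated background fluctuations act as genuine random
slope variance, which the joint df-4 LRT rightly detects — a property of
the test, documented rather than hidden.

## Known limitations

- EDF export is a minimal single-record 16-bit writer (sufficient for
  interchange; no annotations); EDF import goes through MNE.
- The decay metric resolves crossings at sample resolution without
  interpolation, consistent with the windowed estimator's granularity.
- The "frequency of maximum power" trace is the raw per-sample argmax;
  smoothing is left to the caller.
- The χ²(df) reference for the LRT is conservative at variance boundaries
  (see above); no mixture correction is applied.
- Multitaper power is an unweighted mean over retained tapers; eigenvalue
  weighting would change estimates only marginally at the eigenvalue ≥ 0.9
  threshold but is not implemented.
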