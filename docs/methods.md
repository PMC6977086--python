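# Methods

## The problem

Sensorimotor beta-band activity (15–28 Hz) decreases in trial-averaged
power during movement preparation. At the single-trial level that
average conceals an event structure: beta activity occurs in transient
high-amplitude bursts, and an average power decrease can arise from at
least three distinct single-trial changes — lower burst amplitude,
shorter bursts, or rarer bursts (longer inter-burst intervals). This
package implements an event-based decomposition that distinguishes those
mechanisms, together with the surrounding study machinery (conventional
time-frequency analysis, cluster permutation statistics, behavioural
analyses, brain–behaviour correlations) and a synthetic cohort generator
with full ground truth.

## The amplitude-envelope HMM

The core detector is a two-state hidden Markov model on the beta-band
amplitude envelope. Each state k has a Gaussian observation model
N(x | μ_k, σ_k²); the state with the larger μ is the "beta state" and
its on-periods are the detected beta events. Because the two states are
mutually exclusive, the duration of a visit to the low state is exactly
the interval between consecutive events.

Inference is batch variational Bayes with conjugate priors:
Normal–Gamma on each state's (mean, precision), symmetric Dirichlet
(concentration 1) on the transition rows and on the initial
distribution. The priors are weakly informative and empirical: prior
mean = data mean, prior precision scale b₀ = data variance with a₀ = 1,
and a small prior pseudo-count β₀ = 0.01 on the mean. The E-step runs
forward–backward with the expected-log natural parameters; the M-step
updates the conjugate posteriors. The variational free energy
F = −ELBO = −log Ẑ + KL(q(θ)‖p(θ)) is recorded every iteration and is
mathematically non-increasing; the tests assert this per iteration.
Convergence is declared when |ΔF| < 1e-6·|F| or after 500 iterations.

Each fit is restarted from several random initialisations (10 by
default) and the restart with the lowest final free energy is accepted.
Restarts initialise per-sample responsibilities by anchoring each state
on a randomly drawn observation (plus Gumbel jitter); fully i.i.d.
random responsibilities are avoided because they place both states at
the data mean, which is a fixed point of the iteration on slowly
switching data. All randomness derives from a single seed through
`numpy.random.SeedSequence`, so identical inputs and seed give an
identical accepted fit.

Decoding uses the posterior-mean parameters as a point estimate:
forward–backward gives the per-sample posterior state probabilities
("Gamma") and max-product dynamic programming gives the Viterbi path.
Exactness of both is verified against brute-force path enumeration on
short sequences. Downstream code addresses states only through
`identify_beta_state` (larger mean), so label switching across restarts
is harmless. No smoothing is applied beyond the HMM transition prior
itself — that temporal regularisation is the method's advantage over
fixed amplitude thresholds, which split high-amplitude periods on every
noise crossing. A median-amplitude threshold detector is provided as a
comparator; it emits the same visit-table format so every downstream
metric applies unchanged.

Degenerate inputs: a constant envelope yields a flagged degenerate fit
with tied states rather than an error; envelopes with negative values
are rejected; sequences shorter than 500 samples are rejected.

## Event metrics

The Viterbi path is run-length encoded into a visit table on a half-open
[onset, offset) sample grid (0-based, seconds at the 100 Hz envelope
rate). Four trial × time metric time-courses are built:

- **fractional occupancy** — the beta-state Gamma, epoched and averaged
  per condition: the probability of being in the beta state at each
  moment of the trial;
- **amplitude** — each beta visit's samples replaced by the visit's mean
  envelope amplitude; low-state samples are *missing*;
- **lifetime** — each beta visit's samples replaced by that visit's
  duration; low-state samples missing;
- **interval** — each low-state visit's samples replaced by that visit's
  duration (the inter-event interval); beta samples missing.

Two deliberate choices here. First, ignored-state samples are missing
values (NaN), never zeros, and condition averages run over contributing
trials only, with the per-time contributing-trial count always reported.
Averaging zeros instead would make the amplitude time-course a copy of
occupancy and defeat the mechanism separation; the zero-inclusive
variant can be recomputed from the reported counts if wanted. Second,
visits are attributed to epoch time points by sample membership, and a
visit straddling the epoch edge contributes its full continuous-data
duration — durations are properties of the continuous recording,
computed before any epoching, exactly as the HMM itself is fitted on
continuous data with no knowledge of task structure.

Note one statistical property of per-sample replacement: sampling a
dwell at a random time point is size-biased (a dwell of length L covers
L samples), so interval/lifetime time-course values sit above the
generative dwell means. The bias is identical across conditions and
groups, so contrasts are unaffected.

## Envelope preprocessing

For raw oscillatory input, the subject-specific beta peak is the largest
local maximum of a 1/f-corrected Welch spectrum inside 15–28 Hz, where
the aperiodic correction is a log–log linear fit over 4–45 Hz excluding
13–30 Hz (so the beta bump cannot bias the fit); if no local maximum
exists the band centre (21.5 Hz) is used and flagged. The signal is
band-passed at peak ± 6 Hz with a zero-phase (forward–backward) FIR
filter whose transition bandwidth is 0.25 × the band half-width — zero
phase so event timing is not shifted — then the analytic-signal
magnitude is taken and resampled to 100 Hz with an anti-aliasing
polyphase filter. The first/last 0.5 s are excluded from HMM fitting to
avoid filter transients (decoding still covers the full record).
Epoch-level artefact rejection fits a robust location (IRLS, Tukey
bisquare, via statsmodels RLM) to per-epoch variance and removes epochs
whose final weight falls below 0.2.

## Spectral analyses

The conventional analysis is a Hanning-tapered sliding-window Fourier
transform: 300 ms windows advanced in 50 ms steps, 4–45 Hz in 0.5 Hz
steps (zero-padded FFT so the grid step is exact), baseline-normalised
per frequency to percent change against the 200 ms pre-cue period, then
averaged over the subject's beta band. The validity check for the HMM
states weights the raw trace by each state's posterior probability and
computes a segmented DPSS multitaper spectrum (2 s segments, ±2 Hz
half-bandwidth, 0–40 Hz), normalised by the squared mean weight so a
constant unit weighting recovers the plain spectrum; the 100 Hz Gamma is
aligned to the raw grid by nearest-sample upsampling.

## Cluster-based permutation statistics

Condition and group contrasts of the metric time-courses are tested with
temporal cluster-based permutation tests: pointwise t values (paired for
early-vs-late within group; two-sample pooled-variance for the group
contrast on early-minus-late differences) are thresholded at a two-sided
cluster alpha of 0.05, contiguous same-sign suprathreshold runs form
clusters scored by summed t ("cluster mass" — the common Fieldtrip-style
default), and the null is the maximum |mass| over 1000 permutations
(per-subject sign flips for paired designs, group relabellings for
independent ones; full enumeration whenever at most 1000 distinct
permutations exist). Reported cluster p-values are one-sided against
that max-statistic null. Missing time points use the contributing
subjects with t degrees of freedom adjusted per time point; all-missing
points are excluded from cluster formation and logged. Monte-Carlo
p-values use the (1 + b)/(1 + m) convention. Calibration is verified
empirically: family-wise error on white-noise nulls (18 vs 18, 120 time
points) lands in [0.03, 0.07] at nominal 0.05, and a 1-SD offset over a
21-sample window is detected in ≥95 % of paired n=18 datasets. No
correction is applied across the four metric time-courses; each is
reported separately.

## Behavioural analyses

Go-trial reaction times are cleaned per subject in a single pass: RTs
outside mean ± 3 SD (bounds computed once, including any outlier) and
anticipatory responses (RT ≤ 100 ms) are removed, with counts reported.
The temporal validity effect is the relative RT difference
100·(RT_invalid − RT_valid)/mean(RT_invalid, RT_valid) for targets at
the early interval; the denominator (mean of the two cell means) is a
configurable choice — only a "relative difference" is prescribed. The
2 (validity, within) × 2 (group, between) mixed ANOVA is computed from
closed-form sums of squares with F(1, N−2) per effect and partial η² =
SS_effect/(SS_effect + SS_error); it is cross-checked against pingouin
in the tests. Correlations are plain Pearson r with the t-based
two-sided p; two independent correlations are compared with Fisher's
r-to-z, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), reporting
both one- and two-sided normal p-values.

## The synthetic cohort generator

The generator is a first-class, tested module that defines the study
conditions. Each subject's envelope is an alternating-renewal on/off
process on the 100 Hz grid. Dwell laws are geometric by default (exactly
Markov, matched to the HMM's assumptions) with a gamma option (shape 2)
as a model-mismatch stress test; both are simulated through the
discrete-time age-dependent hazard of the discretised law, so
time-varying modulation can scale the per-sample off→on switching
probability. Envelope samples are truncated-at-zero Gaussians around
μ_on = 2.5 / μ_off = 1.0 (SD 0.4), matching the HMM's observation model;
a moment-matched lognormal is the mismatch option. Defaults: mean
lifetime 0.15 s (matching the ~150–160 ms event durations the method
reports on real motor MEG), mean interval 0.40 s, 18 subjects per group,
150 trials per condition (6 blocks of 50 in the emulated task), 80 %
cue validity, 80 % Go targets, 3–5 s inter-trial intervals.

Task coupling is injected *only* through the interval process: during
the anticipatory window (0.2–1.2 s post cue) the mean interval is scaled
by a linear ramp from 1 up to a condition gain — 2.0 for expect-early
cues, 1.25 for expect-late — and resets to 1 outside anticipatory
windows. The gains are free parameters (the source study reports no
numeric burst statistics); 2.0 was chosen so the interval roughly
doubles at the point of maximal preparation, a strong but physiological
modulation, with the late-cue gain well below it since preparation for a
late target is weaker in the early window. The PD-like group's ramp
excess (gain − 1) is scaled by 0.4. Per-subject heterogeneity
multiplies the ramp excess by a subject factor ~ N(1, 0.25) truncated at
zero; that between-subject variance is what gives the brain–behaviour
correlations recoverable structure. On-dwell and amplitude statistics
are never modulated, so rarer events are the sole injected mechanism and
the pipeline can be scored on attributing the occupancy decrease to the
interval metric alone.

Reaction times follow RT = base − coupling·m·[valid] + cost·[invalid] +
noise, with base 430 ms, coupling 30 ms per unit of the subject's
modulation index m (the early-minus-late ramp excess), invalid-cue cost
20 ms, and 50 ms Gaussian noise, floored at 150 ms. Larger neural
modulation therefore predicts both faster valid-trial RTs and a larger
validity effect, mirroring the qualitative correlation pattern of
interest. Raw mode multiplies the (polyphase-upsampled) envelope onto a
21.5 Hz sinusoidal carrier and adds 1/f background noise at a stated
signal-to-noise variance ratio.

A master seed drives everything; per-subject sub-seeds are derived by a
counter-based `SeedSequence` spawn and recorded in the cohort manifest.

What the generator does *not* emulate: multichannel field topographies,
sensor geometry or head movement; non-stationary 1/f backgrounds;
amplitude–duration coupling within bursts; waveform asymmetries. Tests
passing on this cohort therefore show that the pipeline recovers the
intended event structure under its own assumptions (and under gamma /
lognormal mismatch options), not that real MEG meets those assumptions.

One measurement note: against the literal sampled envelope, recovery
correlation from raw mode saturates near 0.78 at any SNR because the
generator's envelope carries i.i.d. within-state amplitude jitter that
no band-limited estimator can reproduce; recovery is therefore assessed
against the state-mean envelope (r ≈ 0.86 at SNR 5), which measures the
burst structure the operation exists to recover.

## Orchestration and problem sizes

`run_pipeline` chains, per subject: envelope (computed from raw or taken
as supplied) → AE-HMM with restarts → state time-courses → visit table →
four metric time-courses → per-condition subject averages; then paired
early-vs-late cluster tests per metric and group, independent
group-difference tests on the early-minus-late contrasts, the
behavioural analysis, and per-group correlations with Fisher
comparisons. An optional post-target window re-runs the metric/contrast
block on a second epoch window via configuration alone. Every table is
persisted as schema-tagged delimited text (visits, trials, long-form
metrics, clusters, correlations round-trip exactly, NaN markers
included), and a line log records seeds, free energies and exclusion
counts. The package is a library: the examples scripts and
`run_pipeline` + stage functions are the interface, and no console entry
point is installed.

Problem sizes in the shipped tests were chosen to exercise the full
study design while staying desk-scale: the mechanism-separation suite
runs 20 cohort replicates at the full design size (18 + 18 subjects,
150 trials per condition, 2 HMM restarts, 1000 permutations); parameter
recovery uses 20 replicates of 6000-sample envelopes; permutation
calibration uses 200 null datasets of 18 vs 18 × 120 time points. Two
restarts suffice in the cohort study because the simulated envelopes are
strongly bimodal and every pilot fit across restarts converged to the
same solution; the default of 10 restarts is kept for general use.

## Known limitations

- The two-state Gaussian observation model is the point of the method,
  but real envelopes are right-skewed; the generator's lognormal option
  probes this mismatch only mildly.
- Very short bursts or gaps (≲ 2 envelope samples) are absorbed by the
  HMM's temporal regularisation; detected lifetimes are upper-biased
  when the generative process produces many sub-resolution dwells, and
  raw-mode band-pass filtering adds further smoothing.
- The closed-form mixed ANOVA assumes two within-levels and two groups;
  it is not a general linear-mixed-model replacement.
- Cluster p-values license inference about the presence of an effect,
  not about exact cluster boundaries.
- Specificity checks on the stationary amplitude metric operate at the
  test's 5 % family-wise level: over a small number of cohort
  replicates, one or a few false amplitude clusters are the expected
  behaviour of a correctly calibrated test, not evidence of an
  amplitude leak (the generator's amplitude statistics are provably
  condition-independent).
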