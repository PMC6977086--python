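# betaevents

Event-based characterisation of motor beta-band activity with a
two-state amplitude-envelope hidden Markov model (AE-HMM).

## The problem

Trial-averaged beta power (15–28 Hz) over sensorimotor cortex decreases
during movement preparation, but at the single-trial level beta activity
is a sequence of transient high-amplitude *events* ("bursts"). A drop in
average power can therefore arise from at least three distinct
single-trial mechanisms:

1. lower event **amplitude**,
2. shorter event **lifetime** (duration), or
3. longer **interval time** between events (a lower event rate).

Distinguishing these matters: in timed movement-preparation tasks, the
interval between events is the parameter that tracks temporal
expectation, and its modulation is selectively reduced in Parkinson's
disease — a group difference invisible in average power. This package
is for researchers who want to run that event-based decomposition on
band-limited amplitude envelopes (M/EEG virtual channels, LFPs) or on
fully synthetic cohorts with known ground truth.

## The model

The beta-band Hilbert envelope x₁…x_T (100 Hz) is modelled by a
two-state HMM with Gaussian observations,

    x_t | z_t = k  ~  N(μ_k, σ_k²),     z_t ∈ {0, 1},

with the state of larger μ_k identified as the **beta state**; its
on-periods are the detected events, and because the two states are
mutually exclusive, a visit to the other state *is* the inter-event
interval. Inference is variational Bayes (Normal–Gamma priors on each
state's mean/precision, Dirichlet priors on the transition rows), run
ten times from random initialisations; the restart with the lowest
variational free energy F = −ELBO is accepted, and F is non-increasing
over iterations by construction. Forward–backward yields the posterior
state probability time-course ("Gamma"), Viterbi decoding the binary
state path; no amplitude threshold is ever chosen, and the HMM's
transition prior provides the temporal regularisation that keeps a
high-amplitude period from being split by every noise dip.

From the decoded path the package derives trial × time metric
time-courses — fractional occupancy, event amplitude, lifetime and
interval time (ignored-state samples are missing values, never zeros) —
and tests condition and group contrasts with temporal cluster-based
permutation tests (summed-t cluster mass against a max-statistic null).
Behavioural analyses (RT outlier exclusion, temporal validity effect,
2×2 mixed ANOVA) and brain–behaviour correlations with Fisher r-to-z
group comparisons complete the pipeline, and a synthetic-cohort
generator with controllable burst statistics, task-locked interval
ramps and RT coupling provides ground truth for all of it. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Detect beta events in a raw oscillatory recording
(`examples/02_detect_beta_events.py`):

```python
import betaevents as be

config = be.SimulationConfig(n_subjects_per_group=1, n_trials=30, seed=0)
rec, trials, truth = be.generate_session(config, "demo", "control", seed=3, mode="raw")

band = be.detect_beta_peak(rec)                      # subject-specific beta peak
env = be.compute_envelope(rec, band, target_fs=100.0)
fit = be.fit_aehmm(env, n_restarts=10, seed=1)       # VB with restarts
stc = be.infer_state_timecourses(fit, env)           # Gamma + Viterbi
visits = be.extract_visits(stc, env)
print(be.summarize_events(visits))
```

which prints:

```
raw recording: 369 s at 250 Hz
detected beta peak: 21.5 Hz -> band (15.5, 27.5) Hz
state means: [1.025 2.199] (beta state = index 1)
accepted restart 8 with free energy 6415.2
beta events: 486 (rate 1.32/s, mean lifetime 237 ms, mean amplitude 2.09)
sample-wise agreement with ground-truth burst state: 92.9 %
```

The detector recovers the simulated carrier frequency (21.5 Hz) and the
two envelope levels (1.0 / 2.5, slightly shrunk by band-limited
smoothing) blindly from the continuous data; 93 % of samples are
assigned to the correct ground-truth burst state. The other examples
cover cohort simulation, the four metric time-courses, cluster
statistics, and the full end-to-end study (`examples/05_full_study.py`),
each printing the numbers it computes and a note on what they mean.

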