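"""Detect beta events in a raw oscillatory recording.

Starts from a raw signal (bursting 21.5 Hz carrier in 1/f noise), finds
the subject-specific beta peak, computes the 100 Hz Hilbert envelope,
fits the two-state amplitude-envelope HMM with restarts, and prints the
fitted observation model and the resulting event summary.
"""

import numpy as np

import betaevents as be

config = be.SimulationConfig(n_subjects_per_group=1, n_trials=30, seed=0)
rec, trials, truth = be.generate_session(config, "demo", "control", seed=3, mode="raw")
print(f"raw recording: {rec.duration:.0f} s at {rec.fs:.0f} Hz")

band = be.detect_beta_peak(rec)
print(f"detected beta peak: {band.peak_freq:.1f} Hz -> band {band.band} Hz")

env = be.compute_envelope(rec, band, target_fs=100.0)
fit = be.fit_aehmm(env, n_restarts=10, seed=1)
beta_state = be.identify_beta_state(fit)
print(f"state means: {np.round(fit.state_means, 3)} (beta state = index {beta_state})")
print(f"accepted restart {fit.best_restart} with free energy {fit.free_energy:.1f}")

stc = be.infer_state_timecourses(fit, env)
visits = be.extract_visits(stc, env)
summary = be.summarize_events(visits)
print(
    f"beta events: {summary['count']} "
    f"(rate {summary['rate_per_s']:.2f}/s, "
    f"mean lifetime {1000 * summary['mean_lifetime_s']:.0f} ms, "
    f"mean amplitude {summary['mean_amplitude']:.2f})"
)

# how well does the blind detection match the simulated ground truth?
overlap = np.mean(stc.viterbi[: truth.true_state_path.size] == truth.true_state_path)
print(f"sample-wise agreement with ground-truth burst state: {100 * overlap:.1f} %")
print(
    "\nThe HMM recovers the two amplitude levels without any threshold\n"
    "choice.  Apparent lifetimes exceed the simulated 150 ms because the\n"
    "band-limited (+/-6 Hz) envelope merges closely spaced bursts; the same\n"
    "smoothing bounds the sample-wise agreement with the ground truth."
)
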