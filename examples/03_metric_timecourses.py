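"""The four beta-state metric time-courses for one subject.

Computes fractional occupancy, amplitude, lifetime and interval-time
time-courses in the anticipatory window (0-1.2 s from cue onset) and
prints their condition averages over the last 200 ms, where temporal
expectation effects are largest.
"""

import numpy as np

import betaevents as be

config = be.SimulationConfig(n_subjects_per_group=1, n_trials=250, seed=0)
rec, trials, truth = be.generate_session(config, "demo", "control", seed=11)

fit = be.fit_aehmm(rec, n_restarts=5, seed=2)
stc = be.infer_state_timecourses(fit, rec)
visits = be.extract_visits(stc, rec)

window = (0.0, 1.2)
tcs = {"occupancy": be.fractional_occupancy_timecourse(stc.gamma, trials, window, fs=rec.fs)}
for metric in ("amplitude", "lifetime", "interval"):
    tcs[metric] = be.metric_timecourse(visits, stc, rec, metric, trials, window)

print(f"{'metric':12s} {'early':>9s} {'late':>9s} {'difference':>11s}")
for metric, tc in tcs.items():
    tail = tc.times >= 1.0
    early = np.nanmean(tc.condition_means["early"][tail])
    late = np.nanmean(tc.condition_means["late"][tail])
    print(f"{metric:12s} {early:9.3f} {late:9.3f} {early - late:+11.3f}")

print(
    "\nThe interval metric carries the condition difference (longer\n"
    "intervals -> rarer events when an early target is expected), while\n"
    "amplitude and lifetime show only single-subject noise: the event-level\n"
    "decomposition of a trial-average 'power' decrease.  Interval values at\n"
    "a time point are size-biased (long intervals cover more samples), so\n"
    "they sit above the 0.4 s generative mean in both conditions.\n"
    "(Units: occupancy is a probability; amplitude is in envelope units;\n"
    "lifetime and interval are seconds.)"
)
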