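"""Simulate a small two-group cohort of burst-structured beta envelopes.

Builds a cohort with the default task coupling (interval-time ramp,
stronger in controls than in the PD-like group), then prints ground-truth
event statistics per group.  The numbers show that only the inter-event
interval is task-modulated: lifetimes and amplitudes are stationary.
"""

import numpy as np

import betaevents as be

config = be.SimulationConfig(n_subjects_per_group=3, n_trials=30, seed=0)
sessions, manifest = be.generate_cohort(config, seed=7)

print(f"cohort: {len(sessions)} sessions "
      f"({manifest['group'].value_counts().to_dict()})")
print(f"{'subject':10s} {'group':8s} {'events':>7s} {'lifetime_ms':>12s} "
      f"{'interval_ms':>12s} {'mod_index':>10s}")
for rec, trials, truth in sessions:
    beta = truth.true_visit_table.beta
    other = truth.true_visit_table.df.query("state == 'other'")
    print(
        f"{rec.subject_id:10s} {rec.group:8s} {len(beta):7d} "
        f"{1000 * beta['duration_s'].mean():12.0f} "
        f"{1000 * other['duration_s'].mean():12.0f} "
        f"{truth.modulation_index:10.2f}"
    )

print(
    "\nLifetimes sit near the configured 150 ms for every subject; intervals\n"
    "average above the stationary 400 ms because the anticipatory ramp\n"
    "suppresses event onsets after each cue.  The modulation index (the\n"
    "subject's early-minus-late ramp excess) is larger for controls: that is\n"
    "the group effect the analysis pipeline is asked to recover."
)
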