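"""The full simulated-cohort study, end to end.

Runs a scaled-down version of the two-group, two-condition study:
simulate, fit HMMs per subject, derive the four metrics, test the
condition and group contrasts, analyse behaviour and correlate brain
with behaviour.  Prints the headline statistics of each stage.
"""

import betaevents as be

config = be.RunConfig(
    simulation=be.SimulationConfig(n_subjects_per_group=8, n_trials=60, seed=0),
    seed=5,
    n_restarts=3,
    n_permutations=500,
)
report = be.run_pipeline(config)

block = report["windows"]["anticipatory"]
print("condition contrasts (expect-early vs expect-late), best cluster p:")
for metric in ("occupancy", "amplitude", "lifetime", "interval"):
    for group in ("control", "pd"):
        res = block["condition_tests"][(metric, group)]
        p = min((c.p_value for c in res.clusters), default=1.0)
        print(f"  {metric:10s} {group:8s} p = {p:.3f}")
    gp = min((c.p_value for c in block["group_tests"][metric].clusters), default=1.0)
    print(f"  {metric:10s} group difference p = {gp:.3f}")

anova = report["behaviour"]["anova"]
print(
    f"\nbehaviour: validity F(1,{anova['validity']['df'][1]}) = "
    f"{anova['validity']['F']:.1f} (p = {anova['validity']['p']:.4f}), "
    f"interaction F = {anova['interaction']['F']:.1f} (p = {anova['interaction']['p']:.3f})"
)

fo = report["correlations"]["interval"]
print(
    f"interval-time vs behaviour: control r = {fo['control']['r']:+.2f}, "
    f"pd r = {fo['pd']['r']:+.2f}, Fisher z = {fo['fisher']['z']:+.2f}"
)
print(
    "\nThe interval contrast is the reliable one (strongest in controls, and\n"
    "carrying the group difference), while amplitude and lifetime stay at\n"
    "chance level, and behaviour shows a clear validity effect.  At this\n"
    "demonstration scale (8 subjects per group) the validity-by-group\n"
    "interaction and the brain-behaviour correlations are underpowered;\n"
    "they emerge at the full study size (18 + 18, 150 trials/condition)."
)
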