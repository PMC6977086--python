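"""Temporal cluster-based permutation testing on metric time-courses.

Simulates subject-level condition contrasts with a late-window effect,
runs the paired cluster test, and shows how the max-statistic null
controls the family-wise error over the time axis.
"""

import numpy as np

import betaevents as be

rng = np.random.default_rng(0)
n_subjects, n_times = 18, 120
times = np.arange(n_times) / 100.0

# per-subject early/late curves; the early condition drifts upward from 0.6 s
late = rng.standard_normal((n_subjects, n_times)) * 0.3
early = rng.standard_normal((n_subjects, n_times)) * 0.3
early[:, 60:] += np.linspace(0, 0.5, 60)

res = be.cluster_permutation_test(
    early, late, design="paired", n_permutations=1000, seed=1, times=times
)
print(f"paired design, {res.n_permutations} permutations")
for c in res.clusters:
    flag = "*" if c.p_value < 0.05 else " "
    print(f"  cluster [{c.start_s:.2f}, {c.end_s:.2f}) s  mass {c.mass:+7.1f}  p = {c.p_value:.3f} {flag}")

null = be.cluster_permutation_test(
    rng.standard_normal((18, 120)), rng.standard_normal((18, 120)),
    design="independent", seed=2, times=times,
)
print(f"\nnull comparison: {len(null.significant)} significant clusters "
      f"out of {len(null.clusters)} formed")
print(
    "\nThe injected late-window drift is recovered as significant\n"
    "positive-mass clusters concentrated after 0.75 s (noise splits the\n"
    "drift into several runs); on pure noise, clusters may form but their\n"
    "max-statistic p-values stay above 0.05 in ~95 % of datasets."
)
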