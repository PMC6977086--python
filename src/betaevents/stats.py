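"""Statistics: temporal cluster permutation tests, behaviour, correlations.

The cluster test controls family-wise error over the time axis with the
max-statistic approach: pointwise t values (paired or two-sample) are
thresholded at a two-sided ``cluster_alpha``; contiguous same-sign
suprathreshold runs form clusters whose mass is the summed t; the null is
the distribution of the maximum absolute cluster mass over sign-flip
(paired) or group-relabelling (independent) permutations.  Reported
cluster p-values are one-sided against that max-|mass| null.  Missing
values (NaN) are handled per time point with degrees of freedom adjusted
to the contributing subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Cluster",
    "ClusterResult",
    "BehaviouralSummary",
    "cluster_permutation_test",
    "exclude_rt_outliers",
    "validity_effect",
    "mixed_anova_2x2",
    "pearson_correlation",
    "fisher_rz_compare",
]


@dataclass
class Cluster:
    start_s: float
    end_s: float          # half-open [start, end)
    mass: float           # summed t over the cluster
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    times: np.ndarray
    design: str
    n_permutations: int
    cluster_alpha: float
    dropped_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]


def _paired_t(diff: np.ndarray):
    """Pointwise one-sample t of per-subject differences, NaN-aware."""
    valid = np.isfinite(diff)
    n = valid.sum(axis=0)
    d0 = np.where(valid, diff, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = d0.sum(axis=0) / n
        var = (d0**2).sum(axis=0) - n * mean**2
        var = np.maximum(var, 0.0) / np.maximum(n - 1, 1)
        t = mean / np.sqrt(var / n)
    t = np.where((var == 0) & (mean == 0), 0.0, t)  # identical conditions
    df = n - 1
    return t, df, n


def _independent_t(a: np.ndarray, b: np.ndarray):
    """Pointwise pooled-variance two-sample t, NaN-aware."""
    out = []
    for x in (a, b):
        valid = np.isfinite(x)
        n = valid.sum(axis=0)
        x0 = np.where(valid, x, 0.0)
        s = x0.sum(axis=0)
        ss = (x0**2).sum(axis=0)
        out.append((n, s, ss))
    (na, sa, ssa), (nb, sb, ssb) = out
    with np.errstate(divide="ignore", invalid="ignore"):
        ma, mb = sa / na, sb / nb
        pooled = (ssa - na * ma**2 + ssb - nb * mb**2) / (na + nb - 2)
        t = (ma - mb) / np.sqrt(pooled * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, na, nb


def _clusters_from_t(t, supra, sign):
    """Contiguous same-sign suprathreshold runs -> (start, stop, mass)."""
    runs = []
    lab = np.where(supra, sign, 0)
    start = None
    cur = 0
    for i, v in enumerate(lab):
        if v != 0 and v == cur:
            continue
        if cur != 0:
            runs.append((start, i, float(t[start:i].sum())))
        start, cur = (i, v) if v != 0 else (None, 0)
    if cur != 0:
        runs.append((start, lab.size, float(t[start:lab.size].sum())))
    return runs


def _max_cluster_mass(t_rows, supra_rows, sign_rows):
    """Max |cluster mass| per permutation row (0 when no cluster forms)."""
    P = t_rows.shape[0]
    out = np.zeros(P)
    for p in range(P):
        runs = _clusters_from_t(t_rows[p], supra_rows[p], sign_rows[p])
        if runs:
            out[p] = max(abs(m) for _, _, m in runs)
    return out


def _enumerate_or_sample_signs(n, n_permutations, rng):
    if 2**n <= n_permutations:
        signs = np.array(list(product([1.0, -1.0], repeat=n)))
        return signs, signs.shape[0], True
    return rng.choice([1.0, -1.0], size=(n_permutations, n)), n_permutations, False


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    design: str = "paired",
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Temporal cluster-based non-parametric permutation test.

    ``a`` and ``b`` are subject x time arrays: the two conditions of each
    subject (``design="paired"``) or the two groups
    (``design="independent"``).  All distinct permutations are enumerated
    when there are at most ``n_permutations`` of them; otherwise a seeded
    Monte-Carlo sample is drawn.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if design not in ("paired", "independent"):
        raise ValueError(f"unknown design {design!r}")
    if a.shape[1] != b.shape[1]:
        raise ValueError("time axes differ")
    if design == "paired" and a.shape[0] != b.shape[0]:
        raise ValueError("paired design needs aligned subjects")
    if min(a.shape[0], b.shape[0]) < 5:
        raise ValueError("need at least 5 subjects per cell")
    T = a.shape[1]
    times = np.arange(T, dtype=float) if times is None else np.asarray(times, float)
    dt = times[1] - times[0] if T > 1 else 1.0
    rng = np.random.default_rng(seed)

    if design == "paired":
        diff = a - b
        mask = np.isfinite(diff)
        t_obs, df, n_t = _paired_t(diff)
    else:
        data = np.vstack([a, b])
        mask = np.isfinite(data)
        t_obs, df, _, _ = _independent_t(a, b)

    dropped = np.flatnonzero(~np.isfinite(t_obs) | (df < 1))
    if dropped.size:
        warnings.warn(f"{dropped.size} time points dropped (insufficient data)")
    tcrit = sps.t.ppf(1 - cluster_alpha / 2, np.maximum(df, 1))
    usable = np.isfinite(t_obs) & (df >= 1)

    supra_obs = usable & (np.abs(t_obs) > tcrit)
    sign_obs = np.sign(np.where(usable, t_obs, 0.0))
    obs_runs = _clusters_from_t(np.where(usable, t_obs, 0.0), supra_obs, sign_obs)

    # --- permutation null of the maximum |cluster mass| ---
    if design == "paired":
        n = diff.shape[0]
        signs, P, exact = _enumerate_or_sample_signs(n, n_permutations, rng)
        d0 = np.where(mask, diff, 0.0)
        sums = signs @ d0                       # (P, T)
        sumsq = (d0**2).sum(axis=0)             # sign-invariant
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = sums / n_t
            var = (sumsq - n_t * mean**2) / np.maximum(n_t - 1, 1)
            t_perm = mean / np.sqrt(var / n_t)
    else:
        n1, n_tot = a.shape[0], a.shape[0] + b.shape[0]
        if comb(n_tot, n1) <= n_permutations:
            labels = np.zeros((comb(n_tot, n1), n_tot))
            for i, c in enumerate(combinations(range(n_tot), n1)):
                labels[i, list(c)] = 1.0
            P, exact = labels.shape[0], True
        else:
            labels = np.zeros((n_permutations, n_tot))
            for i in range(n_permutations):
                labels[i, rng.permutation(n_tot)[:n1]] = 1.0
            P, exact = n_permutations, False
        x0 = np.where(mask, data, 0.0)
        x0sq = x0**2
        m = mask.astype(float)
        na = labels @ m
        sa = labels @ x0
        ssa = labels @ x0sq
        nb_ = m.sum(axis=0) - na
        sb = x0.sum(axis=0) - sa
        ssb = x0sq.sum(axis=0) - ssa
        with np.errstate(divide="ignore", invalid="ignore"):
            ma_, mb_ = sa / na, sb / nb_
            pooled = (ssa - na * ma_**2 + ssb - nb_ * mb_**2) / (na + nb_ - 2)
            t_perm = (ma_ - mb_) / np.sqrt(pooled * (1 / na + 1 / nb_))

    t_perm = np.where(usable[None, :], np.nan_to_num(t_perm), 0.0)
    supra_perm = np.abs(t_perm) > tcrit[None, :]
    sign_perm = np.sign(t_perm)
    null = _max_cluster_mass(t_perm, supra_perm, sign_perm)

    clusters = []
    for start, stop, mass in obs_runs:
        if exact:
            p = float(np.mean(null >= abs(mass)))
            p = max(p, 1.0 / null.size)
        else:
            p = float((1 + np.sum(null >= abs(mass))) / (1 + null.size))
        clusters.append(
            Cluster(
                start_s=float(times[start]),
                end_s=float(times[stop - 1] + dt),
                mass=mass,
                p_value=p,
            )
        )
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        times=times,
        design=design,
        n_permutations=int(null.size),
        cluster_alpha=cluster_alpha,
        dropped_times=dropped,
    )


# ---------------------------------------------------------------------------
# behavioural analyses


def exclude_rt_outliers(
    trials: pd.DataFrame,
    anticipatory_floor_ms: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject RT cleaning: mean +/- 3 SD (single pass) and an anticipatory floor.

    Bounds are computed once from all of a subject's Go RTs (including any
    outlier) and applied with strict inequality.  Returns the cleaned
    trial table and a per-subject exclusion-count table.
    """
    trials = trials.copy()
    keep = np.ones(len(trials), dtype=bool)
    counts = []
    has_rt = trials["rt_ms"].notna() & (trials["target"] == "go")
    for subject, sub in trials[has_rt].groupby("subject"):
        rts = sub["rt_ms"].to_numpy(dtype=float)
        if rts.size < 2:
            warnings.warn(f"subject {subject}: fewer than 2 RTs, outlier pass skipped")
            counts.append({"subject": subject, "sd_excluded": 0, "anticipatory": 0})
            continue
        m, sd = rts.mean(), rts.std(ddof=1)
        sd_out = (rts < m - 3 * sd) | (rts > m + 3 * sd)
        antic = rts <= anticipatory_floor_ms
        drop = sub.index[sd_out | antic]
        keep[trials.index.get_indexer(drop)] = False
        counts.append(
            {
                "subject": subject,
                "sd_excluded": int(sd_out.sum()),
                "anticipatory": int((antic & ~sd_out).sum()),
            }
        )
    return trials[keep], pd.DataFrame(counts)


@dataclass
class BehaviouralSummary:
    per_subject: pd.DataFrame   # subject, group, mean RT per validity, effect %
    excluded: pd.DataFrame
    flagged_subjects: list[str] = field(default_factory=list)


def validity_effect(
    trials: pd.DataFrame,
    interval: str = "early",
    excluded: pd.DataFrame | None = None,
) -> BehaviouralSummary:
    """Relative RT benefit of a valid temporal cue at the given target interval.

    Per subject: ``100 * (RT_invalid - RT_valid) / mean(RT_invalid, RT_valid)``
    over correct Go trials whose target appeared at ``interval``; positive
    values mean faster responses after valid cues.
    """
    sel = (
        (trials["target"] == "go")
        & trials["rt_ms"].notna()
        & (trials["target_time"] == interval)
    )
    rows, flagged = [], []
    for (subject,), sub in trials[sel].groupby(["subject"]):
        cell = sub.groupby("validity")["rt_ms"].mean()
        if "valid" not in cell or "invalid" not in cell:
            flagged.append(subject)
            continue
        v, iv = float(cell["valid"]), float(cell["invalid"])
        rows.append(
            {
                "subject": subject,
                "group": sub["group"].iloc[0],
                "rt_valid_ms": v,
                "rt_invalid_ms": iv,
                "effect_pct": 100.0 * (iv - v) / ((iv + v) / 2.0),
            }
        )
    if flagged:
        warnings.warn(f"subjects with an empty validity cell excluded: {flagged}")
    return BehaviouralSummary(
        per_subject=pd.DataFrame(rows),
        excluded=excluded if excluded is not None else pd.DataFrame(),
        flagged_subjects=flagged,
    )


def mixed_anova_2x2(values: np.ndarray, groups: np.ndarray) -> dict:
    """2 (within) x 2 (between) mixed ANOVA from closed-form sums of squares.

    ``values`` is subject x 2 (the within-factor cells, e.g. valid /
    invalid mean RT); ``groups`` labels each subject's group.  Returns F,
    p and partial eta squared for the within effect, the between effect
    and their interaction, each on (1, N-2) degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be subject x 2 (two within levels)")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    N = values.shape[0]
    grand = values.mean()
    subj_mean = values.mean(axis=1)
    within_mean = values.mean(axis=0)

    ss_between, ss_subj, ss_inter, ss_err = 0.0, 0.0, 0.0, 0.0
    for g in labels:
        sel = groups == g
        ng = int(sel.sum())
        gm = values[sel].mean()
        ss_between += 2 * ng * (gm - grand) ** 2
        ss_subj += 2 * np.sum((subj_mean[sel] - gm) ** 2)
        cell = values[sel].mean(axis=0)
        ss_inter += ng * np.sum((cell - gm - within_mean + grand) ** 2)
        resid = values[sel] - subj_mean[sel][:, None] - cell[None, :] + gm
        ss_err += np.sum(resid**2)
    ss_within = N * np.sum((within_mean - grand) ** 2)

    df_err = N - 2
    out = {}
    for name, ss_effect, ss_error in (
        ("validity", ss_within, ss_err),
        ("group", ss_between, ss_subj),
        ("interaction", ss_inter, ss_err),
    ):
        ms_err = ss_error / df_err
        F = (ss_effect / 1) / ms_err if ms_err > 0 else 0.0
        out[name] = {
            "F": float(F),
            "df": (1, df_err),
            "p": float(sps.f.sf(F, 1, df_err)) if ms_err > 0 else 1.0,
            "partial_eta_sq": float(ss_effect / (ss_effect + ss_error))
            if (ss_effect + ss_error) > 0
            else 0.0,
        }
    return out


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need aligned samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Difference of two independent correlations via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); both the
    one-sided (observed direction) and two-sided normal p are reported.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return {
        "z": float(z),
        "p_one_sided": float(sps.norm.sf(abs(z))),
        "p_two_sided": float(2 * sps.norm.sf(abs(z))),
    }
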