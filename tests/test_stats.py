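"""Cluster permutation tests, behavioural analyses, ANOVA, correlations."""

import numpy as np
import pandas as pd
import pytest

from betaevents import (
    cluster_permutation_test,
    exclude_rt_outliers,
    fisher_rz_compare,
    mixed_anova_2x2,
    pearson_correlation,
    validity_effect,
)


def rt_table(rts_by_subject, **extra):
    rows = []
    for subject, rts in rts_by_subject.items():
        for i, rt in enumerate(rts):
            rows.append(
                {
                    "subject": subject,
                    "group": extra.get("group", "control"),
                    "trial": i,
                    "condition": "early",
                    "validity": extra.get("validity", ["valid"] * len(rts))[i]
                    if isinstance(extra.get("validity"), list)
                    else "valid",
                    "target": "go",
                    "target_time": "early",
                    "rt_ms": rt,
                    "correct": True,
                }
            )
    return pd.DataFrame(rows)


class TestClusterPermutation:
    def test_null_self_comparison(self, rng):
        a = rng.standard_normal((10, 50))
        res = cluster_permutation_test(a, a.copy(), design="paired", seed=0)
        assert np.allclose(res.t_values, 0.0)
        assert res.clusters == []

    def test_detects_injected_offset(self, rng):
        a = rng.standard_normal((18, 120))
        b = a + rng.standard_normal((18, 120)) * 0.3
        b[:, 40:61] += 1.0
        res = cluster_permutation_test(b, a, design="paired", seed=1, times=np.arange(120.0))
        sig = [c for c in res.clusters if c.p_value < 0.05]
        assert any(c.start_s <= 60 and c.end_s >= 40 for c in sig)
        assert all(c.mass > 0 for c in sig)

    def test_independent_design(self, rng):
        a = rng.standard_normal((18, 60)) + 1.0  # global offset
        b = rng.standard_normal((18, 60))
        res = cluster_permutation_test(a, b, design="independent", seed=2)
        assert any(c.p_value < 0.05 for c in res.clusters)

    def test_exact_enumeration_small_n(self, rng):
        a = rng.standard_normal((6, 20))
        b = rng.standard_normal((6, 20))
        res = cluster_permutation_test(a, b, design="paired", n_permutations=1000, seed=3)
        assert res.n_permutations == 2**6

    def test_time_relabelling_invariance(self, rng):
        """A common permutation of the time axis permutes clusters but cannot
        change the pointwise t values it is built from."""
        a = rng.standard_normal((12, 40))
        b = rng.standard_normal((12, 40))
        perm = rng.permutation(40)
        r1 = cluster_permutation_test(a, b, design="paired", seed=4)
        r2 = cluster_permutation_test(a[:, perm], b[:, perm], design="paired", seed=4)
        np.testing.assert_allclose(np.sort(r1.t_values), np.sort(r2.t_values))

    def test_missing_values_handled(self, rng):
        a = rng.standard_normal((10, 30))
        b = rng.standard_normal((10, 30))
        a[:, 5] = np.nan  # all-missing time point
        a[0, 10] = np.nan  # partially missing
        with pytest.warns(UserWarning, match="dropped"):
            res = cluster_permutation_test(a, b, design="paired", seed=5)
        assert 5 in res.dropped_times.tolist()
        assert np.isfinite(res.t_values[10])

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="5"):
            cluster_permutation_test(
                rng.standard_normal((3, 10)), rng.standard_normal((3, 10))
            )


class TestExcludeRtOutliers:
    def test_gross_outlier_removed(self):
        trials = rt_table({"s1": [400.0] * 29 + [5000.0]})
        clean, counts = exclude_rt_outliers(trials)
        assert len(clean) == 29
        assert counts.iloc[0]["sd_excluded"] == 1

    def test_identical_rts_none_removed(self):
        trials = rt_table({"s1": [400.0] * 20})
        clean, _ = exclude_rt_outliers(trials)
        assert len(clean) == 20

    def test_anticipatory_floor(self):
        trials = rt_table({"s1": [400.0, 410.0, 390.0, 50.0]})
        clean, counts = exclude_rt_outliers(trials, anticipatory_floor_ms=100.0)
        assert 50.0 not in clean["rt_ms"].to_numpy()
        assert counts.iloc[0]["anticipatory"] == 1

    def test_single_rt_subject_skipped_with_warning(self):
        trials = rt_table({"s1": [400.0]})
        with pytest.warns(UserWarning, match="fewer than 2"):
            clean, _ = exclude_rt_outliers(trials)
        assert len(clean) == 1


class TestValidityEffect:
    def _table(self, valid_rts, invalid_rts):
        rows = []
        for rt in valid_rts:
            rows.append({"subject": "s1", "group": "control", "validity": "valid",
                         "target": "go", "target_time": "early", "rt_ms": rt, "correct": True})
        for rt in invalid_rts:
            rows.append({"subject": "s1", "group": "control", "validity": "invalid",
                         "target": "go", "target_time": "early", "rt_ms": rt, "correct": True})
        return pd.DataFrame(rows)

    def test_equal_means_zero_effect(self):
        out = validity_effect(self._table([400, 420], [410, 410]))
        assert out.per_subject.iloc[0]["effect_pct"] == pytest.approx(0.0)

    def test_worked_arithmetic(self):
        out = validity_effect(self._table([400.0], [440.0]))
        assert out.per_subject.iloc[0]["effect_pct"] == pytest.approx(100 * 40 / 420)

    def test_scale_invariance(self):
        e1 = validity_effect(self._table([400.0, 410.0], [430.0, 450.0]))
        e2 = validity_effect(self._table([800.0, 820.0], [860.0, 900.0]))
        assert e1.per_subject.iloc[0]["effect_pct"] == pytest.approx(
            e2.per_subject.iloc[0]["effect_pct"]
        )

    def test_empty_cell_flagged(self):
        with pytest.warns(UserWarning, match="empty validity cell"):
            out = validity_effect(self._table([400.0, 420.0], []))
        assert out.flagged_subjects == ["s1"]
        assert out.per_subject.empty


class TestMixedAnova:
    def test_all_equal_zero_f(self):
        values = np.full((8, 2), 5.0)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        out = mixed_anova_2x2(values, groups)
        for eff in out.values():
            assert eff["F"] == pytest.approx(0.0)

    def test_toy_dataset_hand_computed(self):
        # 4 subjects, 2 per group; within levels (v1, v2)
        values = np.array([[10.0, 12.0], [14.0, 18.0], [20.0, 20.0], [24.0, 26.0]])
        groups = np.array(["a", "a", "b", "b"])
        out = mixed_anova_2x2(values, groups)
        # hand-computed sums of squares:
        # grand = 18;  group means a=13.5, b=22.5 -> SS_group = 2*2*(4.5^2)*2 = 162
        # subject means 11,16,20,25 -> SS_subj = 2*((11-13.5)^2+(16-13.5)^2+(20-22.5)^2+(25-22.5)^2) = 50
        # within means (17, 19) -> SS_validity = 4*(1+1) = 8
        # cell means a: (12,15), b: (22,23); interaction dev a: (12-13.5-17+18)= -0.5 ...
        # SS_inter = 2*(0.25+0.25) + 2*(0.25+0.25) = 2;  SS_err = 8*0.25 = 2, df_err = 2
        assert out["group"]["F"] == pytest.approx((162 / 1) / (50 / 2))
        assert out["validity"]["F"] == pytest.approx(8 / (2 / 2))
        assert out["interaction"]["F"] == pytest.approx(2 / (2 / 2))
        assert out["validity"]["partial_eta_sq"] == pytest.approx(8 / (8 + 2))

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 12
        values = rng.normal(500, 40, (n, 2))
        values[n // 2 :, 1] += 25
        groups = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        mine = mixed_anova_2x2(values, groups)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "group": np.repeat(groups, 2),
                "validity": np.tile(["v", "i"], n),
                "rt": values.ravel(),
            }
        )
        ref = pg.mixed_anova(
            data=df, dv="rt", within="validity", between="group", subject="subject"
        ).set_index("Source")
        assert mine["group"]["F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert mine["validity"]["F"] == pytest.approx(ref.loc["validity", "F"], rel=1e-6)
        assert mine["interaction"]["F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_constant_shift_per_subject_leaves_interaction(self, rng):
        values = rng.normal(0, 1, (10, 2))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        shifted = values + rng.normal(0, 5, (10, 1))
        f1 = mixed_anova_2x2(values, groups)["interaction"]["F"]
        f2 = mixed_anova_2x2(shifted, groups)["interaction"]["F"]
        assert f1 == pytest.approx(f2)

    def test_scale_invariance(self, rng):
        values = rng.normal(10, 2, (8, 2))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        o1 = mixed_anova_2x2(values, groups)
        o2 = mixed_anova_2x2(values * 2.0, groups)
        for k in o1:
            assert o1[k]["F"] == pytest.approx(o2[k]["F"])
            assert o1[k]["partial_eta_sq"] == pytest.approx(o2[k]["partial_eta_sq"])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_orthogonal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        y = y - y.mean()
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        cov = np.mean((x - 3) * (y - 3))
        r_hand = cov / (x.std() * y.std())
        r, _ = pearson_correlation(x, y)
        assert r == pytest.approx(r_hand)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestFisherRZ:
    @pytest.mark.parametrize(
        "r1,r2,expected_z",
        [
            (-0.73, 0.27, -3.3),   # fractional occupancy group comparison
            (-0.58, 0.35, -2.82),  # beta-state lifetime
            (0.72, 0.04, 2.38),    # beta-state interval time
            (-0.75, -0.49, -1.2),  # beta power
        ],
    )
    def test_printed_group_comparisons(self, r1, r2, expected_z):
        out = fisher_rz_compare(r1, 18, r2, 18)
        assert out["z"] == pytest.approx(expected_z, abs=0.005 * max(1, abs(expected_z) * 10))

    def test_equal_correlations_zero(self):
        assert fisher_rz_compare(0.5, 20, 0.5, 30)["z"] == 0.0

    def test_antisymmetry(self):
        a = fisher_rz_compare(0.6, 15, -0.2, 25)
        b = fisher_rz_compare(-0.2, 25, 0.6, 15)
        assert a["z"] == pytest.approx(-b["z"])

    @pytest.mark.parametrize("bad", [(1.0, 18, 0.2, 18), (0.5, 3, 0.2, 18)])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fisher_rz_compare(*bad)
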