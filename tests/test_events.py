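"""Visit tables, metric time-courses, summaries, median-threshold comparator."""

import numpy as np
import pandas as pd
import pytest

from betaevents import (
    extract_visits,
    fractional_occupancy_timecourse,
    median_threshold_events,
    metric_timecourse,
    summarize_events,
)
from betaevents.aehmm import StateTimeCourses
from betaevents.events import VisitTable


def stc_from_path(path, fs=100.0):
    path = np.asarray(path)
    gamma = np.column_stack([1.0 - path, path]).astype(float)
    return StateTimeCourses(gamma=gamma, viterbi=path.astype(np.int64), fs=fs)


def trial_table(cue_onsets, conditions=None):
    n = len(cue_onsets)
    conditions = conditions or ["early"] * n
    return pd.DataFrame(
        {
            "subject": ["s"] * n,
            "condition": conditions,
            "cue_onset_s": cue_onsets,
        }
    )


class TestExtractVisits:
    def test_manual_run_length_encoding(self):
        """Path 0011100111 at 100 Hz: two beta visits of 0.03 s separated by
        a 0.02 s other-state visit (the inter-event interval)."""
        path = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1, 1])
        stc = stc_from_path(path)
        visits = extract_visits(stc, np.ones(10))
        beta = visits.beta.reset_index(drop=True)
        assert len(beta) == 2
        assert beta.loc[0, "onset_s"] == pytest.approx(0.02)
        assert beta.loc[0, "offset_s"] == pytest.approx(0.05)
        assert beta.loc[1, "onset_s"] == pytest.approx(0.07)
        assert np.allclose(beta["duration_s"], 0.03)
        between = visits.df.query("state == 'other'").iloc[1]
        assert between["onset_s"] == pytest.approx(0.05)
        assert between["duration_s"] == pytest.approx(0.02)

    def test_all_ones_single_visit(self):
        stc = stc_from_path(np.ones(250))
        visits = extract_visits(stc, np.ones(250))
        assert len(visits.df) == 1
        assert visits.df.iloc[0]["state"] == "beta"
        assert visits.df.iloc[0]["duration_s"] == pytest.approx(2.5)

    def test_visit_mean_amplitude(self):
        path = np.array([0, 1, 1, 0])
        env = np.array([9.0, 2.0, 2.0, 9.0])
        visits = extract_visits(stc_from_path(path), env)
        assert visits.beta.iloc[0]["mean_amp"] == pytest.approx(2.0)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            extract_visits(stc_from_path(np.ones(5)), np.ones(4))

    def test_durations_partition_record(self, rng):
        path = (rng.random(500) < 0.4).astype(int)
        visits = extract_visits(stc_from_path(path), rng.random(500) + 1)
        assert visits.df["duration_s"].sum() == pytest.approx(5.0)
        states = visits.df["state"].to_list()
        assert all(a != b for a, b in zip(states, states[1:]))  # alternation


class TestFractionalOccupancy:
    def test_constant_gamma_one(self):
        gamma = np.ones(300)
        tc = fractional_occupancy_timecourse(gamma, trial_table([0.5, 1.0]), window=(0, 1.0))
        assert np.allclose(tc.condition_means["early"], 1.0)

    def test_mean_over_trials(self):
        gamma = np.concatenate([np.full(100, 0.2), np.full(100, 0.6), np.zeros(100)])
        tc = fractional_occupancy_timecourse(gamma, trial_table([0.0, 1.0]), window=(0, 1.0))
        assert np.allclose(tc.condition_means["early"], 0.4)

    def test_trial_window_outside_recording(self):
        with pytest.raises(ValueError, match=r"trials \[1\]"):
            fractional_occupancy_timecourse(
                np.ones(100), trial_table([0.0, 5.0]), window=(0, 0.5)
            )


class TestMetricTimecourse:
    def test_amplitude_replacement_rule(self):
        """One beta visit of amplitude 2.5 over [0.10, 0.20) s: the amplitude
        track equals 2.5 on those samples and is missing elsewhere."""
        path = np.zeros(40, dtype=int)
        path[10:20] = 1
        env = np.where(path == 1, 2.5, 0.7)
        stc = stc_from_path(path)
        visits = extract_visits(stc, env)
        tc = metric_timecourse(visits, stc, env, "amplitude", trial_table([0.0]), window=(0, 0.4))
        row = tc.values[0]
        assert np.allclose(row[10:20], 2.5)
        assert np.all(np.isnan(row[:10])) and np.all(np.isnan(row[20:]))

    def test_single_contributing_trial(self):
        # at t in [0.0, 0.04) only trial 1 is in the beta state
        path = np.zeros(120, dtype=int)
        path[50:54] = 1  # lifetime 0.04 s within trial 1's window
        stc = stc_from_path(path)
        env = np.ones(120)
        visits = extract_visits(stc, env)
        trials = trial_table([0.0, 0.5])
        tc = metric_timecourse(visits, stc, env, "lifetime", trials, window=(0, 0.1))
        assert tc.condition_means["early"][0] == pytest.approx(0.04)
        assert tc.condition_counts["early"][0] == 1

    def test_no_contributor_is_missing(self):
        path = np.zeros(100, dtype=int)
        path[:2] = 1  # keep both states present
        stc = stc_from_path(path)
        visits = extract_visits(stc, np.ones(100))
        tc = metric_timecourse(
            visits, stc, np.ones(100), "amplitude", trial_table([0.1]), window=(0, 0.5)
        )
        assert np.all(np.isnan(tc.condition_means["early"][10:]))
        assert np.all(tc.condition_counts["early"][10:] == 0)

    def test_interval_track_is_other_state_duration(self):
        path = np.array([1, 0, 0, 0, 1, 1, 0, 0, 0, 0])
        stc = stc_from_path(path)
        env = np.ones(10)
        visits = extract_visits(stc, env)
        tc = metric_timecourse(visits, stc, env, "interval", trial_table([0.0]), window=(0, 0.1))
        row = tc.values[0]
        assert np.isnan(row[0])  # beta sample ignored
        assert np.allclose(row[1:4], 0.03)
        assert np.all(np.isnan(row[4:6]))
        assert np.allclose(row[6:], 0.04)

    def test_straddling_visit_contributes_full_duration(self):
        # beta visit [0.05, 0.25) straddles the epoch end at 0.1 s: samples
        # inside the window must carry the full 0.2 s lifetime
        path = np.zeros(40, dtype=int)
        path[5:25] = 1
        stc = stc_from_path(path)
        visits = extract_visits(stc, np.ones(40))
        tc = metric_timecourse(
            visits, stc, np.ones(40), "lifetime", trial_table([0.0]), window=(0, 0.1)
        )
        assert np.allclose(tc.values[0][5:], 0.2)

    def test_invalid_metric_rejected(self):
        path = np.array([0, 1] * 10)
        stc = stc_from_path(path)
        visits = extract_visits(stc, np.ones(20))
        with pytest.raises(ValueError, match="invalid metric"):
            metric_timecourse(visits, stc, np.ones(20), "power", trial_table([0.0]), window=(0, 0.1))


class TestSummarizeEvents:
    def test_two_visit_window(self):
        path = np.array([0, 0, 1, 1, 1, 0, 0, 1, 1, 1])
        visits = extract_visits(stc_from_path(path), np.ones(10))
        s = summarize_events(visits, window=(0, 0.10))
        assert s["count"] == 2
        assert s["mean_lifetime_s"] == pytest.approx(0.03)
        assert s["rate_per_s"] == pytest.approx(20.0)

    def test_empty_window(self):
        path = np.array([0, 0, 1, 1, 0])
        visits = extract_visits(stc_from_path(path), np.ones(5))
        s = summarize_events(visits, window=(10.0, 11.0))
        assert s["count"] == 0
        assert s["rate_per_s"] == 0.0
        assert np.isnan(s["mean_lifetime_s"])

    def test_window_counts_are_additive(self, rng):
        path = (rng.random(1000) < 0.3).astype(int)
        visits = extract_visits(stc_from_path(path), np.ones(1000))
        whole = summarize_events(visits, window=(0, 10.0))["count"]
        parts = sum(
            summarize_events(visits, window=(i, i + 1.0))["count"] for i in range(10)
        )
        assert whole == parts


class TestMedianThreshold:
    def test_square_wave_blocks_detected(self):
        env = np.tile(np.concatenate([np.ones(10), np.full(10, 3.0)]), 5)
        visits = median_threshold_events(env, fs=100.0)
        beta = visits.beta
        assert len(beta) == 5
        assert np.allclose(beta["duration_s"], 0.1)
        assert np.allclose(beta["mean_amp"], 3.0)

    def test_constant_envelope_no_events(self):
        visits = median_threshold_events(np.full(100, 2.0), fs=100.0)
        assert len(visits.beta) == 0

    def test_agrees_with_hmm_on_clean_square_wave(self):
        """On a noiseless two-level square wave both detectors reduce to
        level classification and give identical visit boundaries."""
        from betaevents import fit_aehmm, infer_state_timecourses

        rng = np.random.default_rng(0)
        env = np.tile(np.concatenate([np.ones(25), np.full(25, 3.0)]), 12)
        env = env + rng.normal(0, 1e-3, env.size)  # break exact degeneracy
        env = np.abs(env)
        fit = fit_aehmm(env, n_restarts=3, seed=0)
        stc = infer_state_timecourses(fit, env)
        hmm_visits = extract_visits(stc, env)
        thr_visits = median_threshold_events(env, fs=100.0)
        pd.testing.assert_frame_equal(
            hmm_visits.df[["state", "onset_s", "offset_s"]],
            thr_visits.df[["state", "onset_s", "offset_s"]],
        )
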