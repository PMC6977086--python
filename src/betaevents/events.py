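"""Beta-event tables and state-metric time-courses.

A decoded binary state path is run-length encoded into a table of state
visits ("beta events" are the visits to the high-amplitude state).  Four
per-trial metric time-courses are derived from the visits and the
posterior state probabilities:

* fractional occupancy - trial-averaged posterior probability of the beta
  state at each epoch time point;
* amplitude - each beta visit's samples carry that visit's mean envelope
  amplitude; other-state samples are missing;
* lifetime - each beta visit's samples carry that visit's duration;
  other-state samples are missing;
* interval - each other-state visit's samples carry that visit's duration
  (the time between consecutive beta events); beta samples are missing.

Missing samples are NaN, never zero, and condition averages are taken
over contributing trials only (the per-time contributing-trial count is
always reported).  Visit durations come from the continuous data before
epoching, so a visit straddling an epoch edge contributes its full
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aehmm import StateTimeCourses
from .envelope import ContinuousRecording

__all__ = [
    "VisitTable",
    "MetricTimeCourse",
    "extract_visits",
    "fractional_occupancy_timecourse",
    "metric_timecourse",
    "summarize_events",
    "median_threshold_events",
    "epoch_samples",
]

METRICS = ("occupancy", "amplitude", "lifetime", "interval")

VISIT_COLUMNS = ["state", "onset_s", "offset_s", "duration_s", "mean_amp"]


@dataclass
class VisitTable:
    """Run-length-encoded state visits on a half-open [onset, offset) grid."""

    df: pd.DataFrame
    fs: float

    def __post_init__(self) -> None:
        missing = [c for c in VISIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"visit table missing columns: {missing}")
        if len(self.df) and not (self.df["duration_s"] > 0).all():
            raise ValueError("visit durations must be positive")

    @property
    def beta(self) -> pd.DataFrame:
        return self.df[self.df["state"] == "beta"]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MetricTimeCourse:
    """Trial x time array of one state metric with NaN missing markers."""

    metric: str
    values: np.ndarray            # (n_trials, n_times), NaN = missing
    times: np.ndarray             # seconds from cue onset
    conditions: np.ndarray        # (n_trials,) condition label per trial
    fs: float
    condition_means: dict[str, np.ndarray] = field(default_factory=dict)
    condition_sems: dict[str, np.ndarray] = field(default_factory=dict)
    condition_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not self.condition_means:
            self._summarise()

    def _summarise(self) -> None:
        import warnings as _w
        for cond in np.unique(self.conditions):
            vals = self.values[self.conditions == cond]
            n = np.sum(np.isfinite(vals), axis=0)
            with _w.catch_warnings():
                _w.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(vals, axis=0)
                sd = np.nanstd(vals, axis=0, ddof=1)
            sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
            self.condition_means[str(cond)] = mean
            self.condition_sems[str(cond)] = sem
            self.condition_counts[str(cond)] = n


def _rle(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an integer sequence into (start, stop, value) runs."""
    path = np.asarray(path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    return [(int(s), int(e), int(path[s])) for s, e in zip(starts, stops)]


def _visits_from_path(path: np.ndarray, amp: np.ndarray, fs: float) -> VisitTable:
    rows = []
    for start, stop, value in _rle(path):
        rows.append(
            {
                "state": "beta" if value == 1 else "other",
                "onset_s": start / fs,
                "offset_s": stop / fs,
                "duration_s": (stop - start) / fs,
                "mean_amp": float(np.mean(amp[start:stop])),
            }
        )
    return VisitTable(pd.DataFrame(rows, columns=VISIT_COLUMNS), fs=fs)


def extract_visits(
    stc: StateTimeCourses,
    envelope: ContinuousRecording | np.ndarray,
) -> VisitTable:
    """Run-length encode the Viterbi path into a visit table.

    Per-visit ``mean_amp`` is the mean envelope amplitude over the visit's
    samples.  Computed on the continuous data, before any epoching.
    """
    amp = envelope.values if isinstance(envelope, ContinuousRecording) else np.asarray(envelope, float)
    if stc.viterbi.size == 0:
        raise ValueError("empty state path")
    if amp.shape[0] != stc.viterbi.shape[0]:
        raise ValueError("envelope and state path lengths differ")
    return _visits_from_path(stc.viterbi, amp, stc.fs)


def epoch_samples(
    n_samples: int,
    cue_onsets_s: np.ndarray,
    window: tuple[float, float],
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Start sample per trial and the shared within-epoch sample offsets.

    Raises (listing the offending trial ids) if any trial window falls
    outside the recording.
    """
    cue_onsets_s = np.asarray(cue_onsets_s, float)
    w = int(round((window[1] - window[0]) * fs))
    starts = np.round((cue_onsets_s + window[0]) * fs).astype(int)
    bad = np.flatnonzero((starts < 0) | (starts + w > n_samples))
    if bad.size:
        raise ValueError(f"trial windows outside recording for trials {bad.tolist()}")
    return starts, np.arange(w)


def _epoch(track: np.ndarray, starts: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    return track[starts[:, None] + offsets[None, :]]


def fractional_occupancy_timecourse(
    gamma: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 1.2),
    fs: float = 100.0,
) -> MetricTimeCourse:
    """Epoch the beta-state Gamma variable into an occupancy time-course.

    ``gamma`` may be the (T, 2) posterior matrix (beta = column 1) or the
    (T,) beta-state probability directly.
    """
    gamma = np.asarray(gamma, float)
    beta_prob = gamma[:, 1] if gamma.ndim == 2 else gamma
    starts, offsets = epoch_samples(beta_prob.size, trials["cue_onset_s"].to_numpy(), window, fs)
    values = _epoch(beta_prob, starts, offsets)
    return MetricTimeCourse(
        metric="occupancy",
        values=values,
        times=window[0] + offsets / fs,
        conditions=trials["condition"].to_numpy(),
        fs=fs,
    )


def _metric_track(
    visits: VisitTable,
    n_samples: int,
    metric: str,
) -> np.ndarray:
    """Continuous per-sample track built by the visit replacement rule."""
    track = np.full(n_samples, np.nan)
    fs = visits.fs
    if metric in ("amplitude", "lifetime"):
        keep_state, column = "beta", ("mean_amp" if metric == "amplitude" else "duration_s")
    else:  # interval
        keep_state, column = "other", "duration_s"
    sub = visits.df[visits.df["state"] == keep_state]
    for onset, offset, value in zip(sub["onset_s"], sub["offset_s"], sub[column]):
        i0 = int(round(onset * fs))
        i1 = min(int(round(offset * fs)), n_samples)
        track[i0:i1] = value
    return track


def metric_timecourse(
    visits: VisitTable,
    stc: StateTimeCourses,
    envelope: ContinuousRecording | np.ndarray,
    metric: str,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 1.2),
) -> MetricTimeCourse:
    """Build a trial x time amplitude/lifetime/interval time-course.

    Samples belonging to the ignored state are NaN, and condition averages
    use contributing trials only.
    """
    if metric not in ("amplitude", "lifetime", "interval"):
        raise ValueError(f"invalid metric {metric!r} (occupancy has its own operation)")
    n = stc.viterbi.size
    track = _metric_track(visits, n, metric)
    starts, offsets = epoch_samples(n, trials["cue_onset_s"].to_numpy(), window, stc.fs)
    values = _epoch(track, starts, offsets)
    return MetricTimeCourse(
        metric=metric,
        values=values,
        times=window[0] + offsets / stc.fs,
        conditions=trials["condition"].to_numpy(),
        fs=stc.fs,
    )


def summarize_events(
    visits: VisitTable,
    window: tuple[float, float] | None = None,
) -> dict:
    """Summary statistics over beta visits whose onset lies in ``window``."""
    beta = visits.beta
    if window is not None:
        w0, w1 = window
        beta = beta[(beta["onset_s"] >= w0) & (beta["onset_s"] < w1)]
        span = w1 - w0
    else:
        span = visits.df["offset_s"].max() - visits.df["onset_s"].min() if len(visits.df) else 0.0
    count = len(beta)
    return {
        "count": count,
        "rate_per_s": count / span if span > 0 else 0.0,
        "mean_lifetime_s": float(beta["duration_s"].mean()) if count else np.nan,
        "mean_amplitude": float(beta["mean_amp"].mean()) if count else np.nan,
    }


def median_threshold_events(
    envelope: ContinuousRecording | np.ndarray,
    fs: float | None = None,
) -> VisitTable:
    """Median-amplitude-threshold comparator for the HMM event detection.

    Beta events are maximal runs of samples strictly above the
    whole-recording median amplitude; the output uses the same visit-table
    format so every downstream metric applies unchanged.
    """
    if isinstance(envelope, ContinuousRecording):
        amp, fs = envelope.values, envelope.fs
    else:
        amp = np.asarray(envelope, float)
        fs = float(fs) if fs is not None else 100.0
    if amp.size == 0:
        raise ValueError("empty envelope")
    path = (amp > np.median(amp)).astype(np.int64)
    return _visits_from_path(path, amp, fs)
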