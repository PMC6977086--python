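"""End-to-end study orchestration on a simulated (or supplied) cohort.

``run_pipeline`` chains, for every subject: amplitude envelope (computed
from raw data or taken as supplied) -> two-state AE-HMM with restarts ->
state time-courses -> visit table -> the four metric time-courses ->
per-condition subject averages; then at the group level: paired
early-vs-late cluster tests per metric and group, independent
group-difference tests on the early-minus-late contrast, the behavioural
validity analysis (outlier exclusion, validity effect, 2x2 mixed ANOVA),
and per-group brain-behaviour correlations with Fisher r-to-z group
comparisons.  Every table is persisted as delimited text and a structured
line log records seeds, free energies and exclusion counts.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from .aehmm import fit_aehmm, infer_state_timecourses
from .envelope import BandSpec, ContinuousRecording, compute_envelope, detect_beta_peak
from .simulate import SimulationConfig, generate_cohort
from .stats import (
    cluster_permutation_test,
    exclude_rt_outliers,
    fisher_rz_compare,
    mixed_anova_2x2,
    pearson_correlation,
    validity_effect,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_table",
    "read_table",
    "write_recording",
    "read_recording",
    "TABLE_SCHEMAS",
]

SCHEMA_VERSION = 1

TABLE_SCHEMAS = {
    "visits": ["state", "onset_s", "offset_s", "duration_s", "mean_amp"],
    "trials": [
        "subject", "group", "trial", "condition", "validity", "target",
        "target_time", "cue_onset_s", "rt_ms", "correct",
    ],
    "metric_long": ["subject", "group", "condition", "metric", "time_s", "value"],
    "clusters": [
        "metric", "contrast", "design", "start_s", "end_s", "mass", "p_value",
    ],
    "correlations": [
        "metric", "group", "r", "p", "n", "fisher_z", "fisher_p_one_sided",
    ],
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a schema-tagged delimited table (CSV with a version header)."""
    cols = TABLE_SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table of kind {kind!r} missing columns: {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# betaevents-table v{SCHEMA_VERSION} kind={kind}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, validating its schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    return df


def write_recording(recording: ContinuousRecording, path: str | Path) -> None:
    """Write a continuous series as two-column delimited text (time_s, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# betaevents-recording v{SCHEMA_VERSION} kind={recording.kind} "
        f"fs={recording.fs} subject={recording.subject_id} "
        f"group={recording.group} channel={recording.channel_label}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("time_s,value\n")
        np.savetxt(fh, np.column_stack([recording.times, recording.values]),
                   fmt="%.6f,%.10g")


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read a continuous series written by :func:`write_recording`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("# betaevents-recording"):
        raise ValueError(f"{path}: not a betaevents recording file")
    meta = dict(tok.split("=", 1) for tok in header.split() if "=" in tok)
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    return ContinuousRecording(
        data[:, 1],
        fs=float(meta["fs"]),
        kind=meta.get("kind", "raw"),
        subject_id=meta.get("subject", ""),
        group=meta.get("group", ""),
        channel_label=meta.get("channel", "roi"),
    )


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    n_restarts: int = 10
    band_half_width: float = 6.0
    anticipatory_window: tuple[float, float] = (0.0, 1.2)
    baseline_window: tuple[float, float] = (-0.2, 0.0)
    post_target_window: tuple[float, float] | None = None
    correlation_window_s: float = 0.2     # last part of the anticipatory window
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    edge_trim_s: float = 0.5              # filter-transient margin excluded from HMM fit
    output_dir: str | None = None
    signal_mode: str = "envelope"         # {"envelope", "raw"}

    def __post_init__(self) -> None:
        for w in (self.anticipatory_window, self.baseline_window, self.post_target_window):
            if w is not None and w[1] <= w[0]:
                raise ValueError(f"window {w} is not well ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("anticipatory_window", "baseline_window", "post_target_window"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


METRICS = ("occupancy", "amplitude", "lifetime", "interval")


class _Log:
    def __init__(self, path: Path | None):
        self.path = path
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{stamp} {msg}")

    def flush(self) -> None:
        if self.path is not None:
            self.path.write_text("\n".join(self.lines) + "\n")


def _subject_metrics(recording, trials, config, sub_seed, window):
    """Envelope -> HMM -> visits -> per-condition mean metric curves."""
    if recording.kind == "raw":
        band = detect_beta_peak(recording)
        env = compute_envelope(recording, band)
    else:
        env = recording

    trim = int(round(config.edge_trim_s * env.fs))
    fit_values = env.values[trim:-trim] if trim and env.values.size > 2 * trim else env.values
    fit = fit_aehmm(
        fit_values, n_restarts=config.n_restarts, seed=sub_seed, fs=env.fs
    )
    stc = infer_state_timecourses(fit, env.values)
    visits = ev.extract_visits(stc, env.values)

    curves = {}
    tcs = {}
    tcs["occupancy"] = ev.fractional_occupancy_timecourse(
        stc.gamma, trials, window=window, fs=env.fs
    )
    for metric in ("amplitude", "lifetime", "interval"):
        tcs[metric] = ev.metric_timecourse(visits, stc, env.values, metric, trials, window=window)
    for metric, tc in tcs.items():
        curves[metric] = {
            cond: tc.condition_means[cond] for cond in ("early", "late")
        }
    return fit, visits, tcs, curves


def _stack(per_subject_curves, group, metric, cond, subjects_by_group):
    return np.vstack(
        [per_subject_curves[s][metric][cond] for s in subjects_by_group[group]]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulated-cohort study; returns the report bundle."""
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log" if outdir else None)
    log(f"pipeline start, master seed {config.seed}")

    sessions, manifest = generate_cohort(
        config.simulation, seed=config.seed, mode=config.signal_mode
    )
    log(f"simulated cohort: {len(sessions)} sessions")

    windows = {"anticipatory": config.anticipatory_window}
    if config.post_target_window is not None:
        windows["post_target"] = config.post_target_window

    subjects_by_group = {"control": [], "pd": []}
    per_curves = {w: {} for w in windows}
    all_trials = []
    stage = "subject"
    ss = np.random.SeedSequence([config.seed, 7])
    sub_seeds = [int(s % 2**31) for s in ss.generate_state(len(sessions))]
    for (recording, trials, _truth), sub_seed in zip(sessions, sub_seeds):
        sid = recording.subject_id
        try:
            subjects_by_group[recording.group].append(sid)
            all_trials.append(trials)
            for wname, window in windows.items():
                fit, visits, _tcs, curves = _subject_metrics(
                    recording, trials, config, sub_seed, window
                )
                per_curves[wname][sid] = curves
                if wname == "anticipatory":
                    log(
                        f"subject {sid}: seed {sub_seed}, "
                        f"free energy {fit.free_energy:.2f} (restart {fit.best_restart})"
                    )
                    if outdir:
                        write_table(visits.df, outdir / f"visits_{sid}.csv", "visits")
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            log.flush()
            raise RuntimeError(f"stage {stage!r} failed for subject {sid}: {exc}") from exc

    trials_all = pd.concat(all_trials, ignore_index=True)
    if outdir:
        write_table(trials_all, outdir / "trials.csv", "trials")

    # --- cluster statistics -------------------------------------------------
    stage = "cluster-stats"
    w = config.anticipatory_window
    n_time = int(round((w[1] - w[0]) * config.simulation.fs_env))
    times = w[0] + np.arange(n_time) / config.simulation.fs_env
    report: dict = {"windows": {}, "manifest": manifest}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]).generate_state(1)[0])
    for wname in windows:
        block = {"condition_tests": {}, "group_tests": {}}
        cluster_rows = []
        for metric in METRICS:
            diffs = {}
            for group in ("control", "pd"):
                early = _stack(per_curves[wname], group, metric, "early", subjects_by_group)
                late = _stack(per_curves[wname], group, metric, "late", subjects_by_group)
                res = cluster_permutation_test(
                    early, late, design="paired",
                    n_permutations=config.n_permutations,
                    cluster_alpha=config.cluster_alpha,
                    seed=int(rng.integers(2**31)),
                    times=times,
                )
                block["condition_tests"][(metric, group)] = res
                diffs[group] = early - late
                for c in res.clusters:
                    cluster_rows.append(
                        {
                            "metric": metric, "contrast": f"early_vs_late_{group}",
                            "design": "paired", "start_s": c.start_s,
                            "end_s": c.end_s, "mass": c.mass, "p_value": c.p_value,
                        }
                    )
            gres = cluster_permutation_test(
                diffs["control"], diffs["pd"], design="independent",
                n_permutations=config.n_permutations,
                cluster_alpha=config.cluster_alpha,
                seed=int(rng.integers(2**31)),
                times=times,
            )
            block["group_tests"][metric] = gres
            for c in gres.clusters:
                cluster_rows.append(
                    {
                        "metric": metric, "contrast": "group_difference",
                        "design": "independent", "start_s": c.start_s,
                        "end_s": c.end_s, "mass": c.mass, "p_value": c.p_value,
                    }
                )
        block["cluster_table"] = pd.DataFrame(
            cluster_rows, columns=TABLE_SCHEMAS["clusters"]
        )
        if outdir:
            write_table(block["cluster_table"], outdir / f"clusters_{wname}.csv", "clusters")
        report["windows"][wname] = block

    # --- behaviour ----------------------------------------------------------
    stage = "behaviour"
    clean, excl = exclude_rt_outliers(trials_all)
    log(f"behaviour: excluded {int(excl.get('sd_excluded', pd.Series()).sum())} SD outliers, "
        f"{int(excl.get('anticipatory', pd.Series()).sum())} anticipatory")
    behav = validity_effect(clean, interval="early", excluded=excl)
    per_subj = behav.per_subject.set_index("subject")
    anova = mixed_anova_2x2(
        per_subj[["rt_valid_ms", "rt_invalid_ms"]].to_numpy(),
        per_subj["group"].to_numpy(),
    )
    report["behaviour"] = {"summary": behav, "anova": anova}

    # --- brain-behaviour correlations ---------------------------------------
    stage = "correlations"
    tail = times >= (w[1] - config.correlation_window_s)
    corr_rows = []
    report["correlations"] = {}
    for metric in METRICS:
        per_group = {}
        for group in ("control", "pd"):
            ids = [s for s in subjects_by_group[group] if s in per_subj.index]
            neural = []
            for s in ids:
                d = (
                    per_curves["anticipatory"][s][metric]["early"]
                    - per_curves["anticipatory"][s][metric]["late"]
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    neural.append(np.nanmean(d[tail]))
            behav_eff = per_subj.loc[ids, "effect_pct"].to_numpy()
            neural = np.asarray(neural)
            ok = np.isfinite(neural)
            if ok.sum() >= 4:
                r, p = pearson_correlation(behav_eff[ok], neural[ok])
            else:
                warnings.warn(f"{metric}/{group}: too few subjects for correlation")
                r, p = np.nan, np.nan
            per_group[group] = {"r": r, "p": p, "n": int(ok.sum())}
        if all(np.isfinite(per_group[g]["r"]) and per_group[g]["n"] > 3 for g in per_group):
            fz = fisher_rz_compare(
                per_group["control"]["r"], per_group["control"]["n"],
                per_group["pd"]["r"], per_group["pd"]["n"],
            )
        else:
            fz = {"z": np.nan, "p_one_sided": np.nan, "p_two_sided": np.nan}
        report["correlations"][metric] = {**per_group, "fisher": fz}
        for group in ("control", "pd"):
            corr_rows.append(
                {
                    "metric": metric, "group": group,
                    "r": per_group[group]["r"], "p": per_group[group]["p"],
                    "n": per_group[group]["n"], "fisher_z": fz["z"],
                    "fisher_p_one_sided": fz["p_one_sided"],
                }
            )
    corr_table = pd.DataFrame(corr_rows, columns=TABLE_SCHEMAS["correlations"])
    report["correlation_table"] = corr_table
    if outdir:
        write_table(corr_table, outdir / "correlations.csv", "correlations")

    log("pipeline complete")
    log.flush()
    report["log"] = log.lines
    return report
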