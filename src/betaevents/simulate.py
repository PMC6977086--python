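"""Synthetic cohorts of burst-structured beta envelopes with task coupling.

Each subject's envelope is an alternating-renewal on/off process sampled
on the 100 Hz envelope grid: "on" dwells are beta events (high-amplitude
truncated-Gaussian samples), "off" dwells are the intervals between
events.  Temporal anticipation is injected exclusively through the
interval process: during the anticipatory window of each trial the mean
off-dwell is scaled by a linear ramp, stronger for expect-early than
expect-late cues and attenuated for the PD-like group.  On-dwell and
amplitude statistics are left untouched, so a task-locked decrease in
beta occupancy/power arises purely from rarer events (mechanism:
increased inter-event interval), and the detection pipeline can be asked
which of the three candidate mechanisms it attributes the change to.

Reaction times are coupled to each subject's ground-truth neural
modulation index so that brain-behaviour correlations have recoverable
structure, and a valid temporal cue speeds responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .envelope import ContinuousRecording
from .events import VisitTable, _visits_from_path

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "raw_from_envelope",
]


@dataclass
class SimulationConfig:
    """Ground-truth knobs of the synthetic cohort.

    Dwell means are in seconds; amplitudes in arbitrary envelope units.
    ``ramp_gain_*`` are the multiplicative maxima the mean interval
    reaches at the end of the anticipatory window (1 = no modulation);
    ``group_gain`` scales the ramp excess (gain - 1) for the PD-like
    group.  ``subject_sd`` adds between-subject variability to the ramp
    so correlational analyses have signal.
    """

    n_subjects_per_group: int = 18
    fs_raw: float = 250.0
    fs_env: float = 100.0
    carrier_freq: float = 21.5
    mu_on: float = 2.5
    mu_off: float = 1.0
    sigma_on: float = 0.4
    sigma_off: float = 0.4
    mean_lifetime_s: float = 0.15
    mean_interval_s: float = 0.40
    dwell_family: str = "geometric"  # {"geometric", "gamma"}
    gamma_shape: float = 2.0
    amplitude_family: str = "truncnorm"  # {"truncnorm", "lognormal"}
    ramp_gain_early: float = 2.0
    ramp_gain_late: float = 1.25
    group_gain: float = 0.4
    subject_sd: float = 0.25
    n_trials: int = 150
    validity: float = 0.80
    go_prob: float = 0.80
    iti_range_s: tuple[float, float] = (3.0, 5.0)
    rt_base_ms: float = 430.0
    rt_noise_ms: float = 50.0
    rt_coupling_ms: float = 30.0
    rt_invalid_cost_ms: float = 20.0
    rt_floor_ms: float = 150.0
    anticipatory_ramp_window: tuple[float, float] = (0.2, 1.2)
    early_target_s: float = 1.2
    late_target_s: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fs_raw", "fs_env", "mu_on", "mu_off", "sigma_on", "sigma_off",
            "mean_lifetime_s", "mean_interval_s", "rt_base_ms", "rt_noise_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.validity <= 1:
            raise ValueError("validity must be in (0, 1]")
        if self.fs_env > self.fs_raw:
            raise ValueError("fs_env must not exceed fs_raw")
        if self.mu_on <= self.mu_off:
            raise ValueError("mu_on must exceed mu_off (beta is the high state)")
        if self.dwell_family not in ("geometric", "gamma"):
            raise ValueError(f"unknown dwell family {self.dwell_family!r}")
        if min(self.ramp_gain_early, self.ramp_gain_late) <= 0:
            raise ValueError("ramp gains must yield positive dwell means")
        if self.mean_lifetime_s * self.fs_env < 1 or self.mean_interval_s * self.fs_env < 1:
            raise ValueError("dwell means must be at least one envelope sample")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_visit_table: VisitTable
    true_state_path: np.ndarray      # binary at fs_env, 1 = burst on
    modulation_index: float          # subject's early-minus-late ramp excess
    ramp: np.ndarray                 # realised per-sample interval scaling
    subject_gains: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# dwell hazards

_HAZARD_LEN = 4096


def _dwell_hazard(mean_s: float, fs: float, family: str, shape: float) -> np.ndarray:
    """Discrete-time hazard h[a] = P(leave after sample a+1 | survived a samples).

    Geometric dwells have a constant hazard (exactly Markov); gamma dwells
    (duration = ceil(G * fs), G ~ Gamma(shape, mean/shape)) have the
    age-dependent hazard of that discretised law.
    """
    if family == "geometric":
        return np.full(_HAZARD_LEN, min(1.0 / (mean_s * fs), 1.0))
    scale = mean_s / shape
    edges = np.arange(_HAZARD_LEN + 1) / fs
    cdf = sps.gamma.cdf(edges, a=shape, scale=scale)
    pmf = np.diff(cdf)
    surv = 1.0 - cdf[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(surv > 1e-12, pmf / surv, 1.0)
    h[-1] = 1.0
    return np.clip(h, 0.0, 1.0)


def _simulate_path(
    n_samples: int,
    on_hazard: np.ndarray,
    off_hazard: np.ndarray,
    ramp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating on/off renewal path; the off->on hazard is divided by
    ``ramp`` (mean interval multiplied), sample by sample."""
    path = np.empty(n_samples, dtype=np.int64)
    u = rng.random(n_samples)
    state = 0
    age = 0
    maxage = on_hazard.size - 1
    for t in range(n_samples):
        path[t] = state
        if state == 1:
            h = on_hazard[min(age, maxage)]
        else:
            h = min(off_hazard[min(age, maxage)] / ramp[t], 1.0)
        if u[t] < h:
            state = 1 - state
            age = 0
        else:
            age += 1
    return path


def _sample_amplitudes(
    path: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = path.size
    env = np.empty(n)
    for value, mu, sigma in (
        (1, config.mu_on, config.sigma_on),
        (0, config.mu_off, config.sigma_off),
    ):
        mask = path == value
        k = int(mask.sum())
        if config.amplitude_family == "lognormal":
            # moment-matched lognormal (model-mismatch option)
            s2 = np.log1p(sigma**2 / mu**2)
            env[mask] = rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2), k)
        else:
            a = (0.0 - mu) / sigma
            env[mask] = sps.truncnorm.rvs(
                a, np.inf, loc=mu, scale=sigma, size=k, random_state=rng
            )
    return env


# ---------------------------------------------------------------------------
# trial schedule and RT model


def _build_trials(
    config: SimulationConfig,
    subject_id: str,
    group: str,
    mod_index: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = config.n_trials
    conditions = np.array(["early"] * n + ["late"] * n)
    rng.shuffle(conditions)
    valid = rng.random(2 * n) < config.validity
    go = rng.random(2 * n) < config.go_prob

    rows = []
    t = 1.0  # lead-in
    for i in range(2 * n):
        cond = conditions[i]
        predicted = config.early_target_s if cond == "early" else config.late_target_s
        other = config.late_target_s if cond == "early" else config.early_target_s
        target_delay = predicted if valid[i] else other
        rt = np.nan
        correct = True
        if go[i]:
            rt = (
                config.rt_base_ms
                - config.rt_coupling_ms * mod_index * valid[i]
                + config.rt_invalid_cost_ms * (not valid[i])
                + rng.normal(0.0, config.rt_noise_ms)
            )
            rt = max(rt, config.rt_floor_ms)
        else:
            correct = bool(rng.random() < 0.9)  # NoGo: withheld response
        rows.append(
            {
                "subject": subject_id,
                "group": group,
                "trial": i,
                "condition": cond,
                "validity": "valid" if valid[i] else "invalid",
                "target": "go" if go[i] else "nogo",
                "target_time": "early" if target_delay == config.early_target_s else "late",
                "cue_onset_s": t,
                "rt_ms": rt,
                "correct": correct,
            }
        )
        response_lag = target_delay + (rt / 1000.0 if np.isfinite(rt) else 0.5)
        t += response_lag + rng.uniform(*config.iti_range_s)
    return pd.DataFrame(rows)


def _ramp_array(
    n_samples: int,
    trials: pd.DataFrame,
    config: SimulationConfig,
    gain_early: float,
    gain_late: float,
) -> np.ndarray:
    """Per-sample multiplicative scaling of the mean inter-event interval.

    Rises linearly from 1 at ramp-window start to the condition gain at
    ramp-window end (post-cue), and is 1 outside anticipatory windows.
    """
    fs = config.fs_env
    w0, w1 = config.anticipatory_ramp_window
    ramp = np.ones(n_samples)
    span = int(round((w1 - w0) * fs))
    for cue, cond in zip(trials["cue_onset_s"], trials["condition"]):
        gain = gain_early if cond == "early" else gain_late
        i0 = int(round((cue + w0) * fs))
        i1 = min(i0 + span, n_samples)
        if i0 >= n_samples:
            continue
        frac = np.arange(i1 - i0) / span
        ramp[i0:i1] = 1.0 + frac * (gain - 1.0)
    return ramp


# ---------------------------------------------------------------------------
# public operations


def generate_session(
    config: SimulationConfig,
    subject_id: str,
    group: str = "control",
    seed: int | None = None,
    mode: str = "envelope",
) -> tuple[ContinuousRecording, pd.DataFrame, GroundTruth]:
    """Simulate one subject: envelope (or raw) signal, trial table, ground truth.

    ``group`` is ``"control"`` or ``"pd"``; the PD-like group's
    anticipatory ramp excess is scaled by ``config.group_gain``.
    """
    if group not in ("control", "pd"):
        raise ValueError(f"unknown group {group!r}")
    if mode not in ("envelope", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    gscale = config.group_gain if group == "pd" else 1.0
    subj = max(rng.normal(1.0, config.subject_sd), 0.0)
    gain_early = 1.0 + (config.ramp_gain_early - 1.0) * gscale * subj
    gain_late = 1.0 + (config.ramp_gain_late - 1.0) * gscale * subj
    mod_index = gain_early - gain_late

    trials = _build_trials(config, subject_id, group, mod_index, rng)

    last_cue = trials["cue_onset_s"].iloc[-1]
    duration_s = last_cue + config.late_target_s + 2.0
    n_samples = int(round(duration_s * config.fs_env))

    ramp = _ramp_array(n_samples, trials, config, gain_early, gain_late)
    on_hazard = _dwell_hazard(
        config.mean_lifetime_s, config.fs_env, config.dwell_family, config.gamma_shape
    )
    off_hazard = _dwell_hazard(
        config.mean_interval_s, config.fs_env, config.dwell_family, config.gamma_shape
    )
    path = _simulate_path(n_samples, on_hazard, off_hazard, ramp, rng)
    env = _sample_amplitudes(path, config, rng)

    truth = GroundTruth(
        true_visit_table=_visits_from_path(path, env, config.fs_env),
        true_state_path=path,
        modulation_index=mod_index,
        ramp=ramp,
        subject_gains={"early": gain_early, "late": gain_late},
    )
    recording = ContinuousRecording(
        env, fs=config.fs_env, kind="envelope",
        subject_id=subject_id, group=group,
    )
    if mode == "raw":
        recording = raw_from_envelope(
            env,
            carrier_freq=config.carrier_freq,
            fs_raw=config.fs_raw,
            fs_env=config.fs_env,
            seed=int(rng.integers(2**31)),
            subject_id=subject_id,
            group=group,
        )
    return recording, trials, truth


def generate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    mode: str = "envelope",
) -> tuple[list[tuple[ContinuousRecording, pd.DataFrame, GroundTruth]], pd.DataFrame]:
    """Simulate both groups; deterministic given ``seed``.

    Per-subject sub-seeds are derived from the master seed by a
    counter-based spawn and recorded in the returned manifest.
    """
    if config.n_subjects_per_group < 1:
        raise ValueError("need at least one subject per group")
    seed = config.seed if seed is None else seed
    sessions = []
    manifest_rows = []
    counter = 0
    for group in ("control", "pd"):
        for i in range(config.n_subjects_per_group):
            sub_seed = int(
                np.random.SeedSequence([seed, counter]).generate_state(1)[0] % (2**31)
            )
            subject_id = f"{group}{i:02d}"
            sessions.append(
                generate_session(config, subject_id, group, seed=sub_seed, mode=mode)
            )
            manifest_rows.append(
                {"subject": subject_id, "group": group, "counter": counter, "seed": sub_seed}
            )
            counter += 1
    return sessions, pd.DataFrame(manifest_rows)


def raw_from_envelope(
    envelope: np.ndarray,
    carrier_freq: float = 21.5,
    noise_exponent: float = 1.0,
    snr: float = 5.0,
    fs_raw: float = 250.0,
    fs_env: float = 100.0,
    seed: int = 0,
    subject_id: str = "",
    group: str = "",
) -> ContinuousRecording:
    """Modulate an envelope onto a sinusoidal carrier in 1/f^a background noise.

    ``snr`` is the ratio of carrier-signal variance to noise variance
    (``np.inf`` for a noiseless signal).
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    if carrier_freq >= fs_raw / 2:
        raise ValueError(f"carrier {carrier_freq} Hz at or above Nyquist of fs_raw {fs_raw} Hz")

    from scipy.signal import resample_poly
    from math import gcd

    up, down = int(fs_raw), int(fs_env)
    g = gcd(up, down)
    env_up = np.maximum(resample_poly(envelope, up // g, down // g), 0.0)

    rng = np.random.default_rng(seed)
    n = env_up.size
    t = np.arange(n) / fs_raw
    phase = rng.uniform(0, 2 * np.pi)
    sig = env_up * np.sin(2 * np.pi * carrier_freq * t + phase)

    if np.isfinite(snr):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1 / fs_raw)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-noise_exponent / 2.0)
        noise = np.fft.irfft(spec * shaping, n=n)
        nv = noise.var()
        if nv > 0:
            noise *= np.sqrt(sig.var() / (snr * nv))
        sig = sig + noise
    return ContinuousRecording(
        sig, fs=fs_raw, kind="raw", subject_id=subject_id, group=group,
    )
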