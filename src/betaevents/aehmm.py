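"""Two-state amplitude-envelope HMM (AE-HMM).

The model describes a beta-band amplitude envelope as alternating visits
to a high-amplitude ("beta") and a low-amplitude ("other") state, each
with a Gaussian observation model.  Inference is batch variational Bayes
with conjugate priors (Normal-Gamma on each state's mean/precision,
Dirichlet on the transition rows and initial distribution).  The
variational free energy F = -ELBO is tracked every iteration and is
non-increasing; the fit is repeated from several random initialisations
and the restart with the lowest final free energy is kept.

The fitted model is summarised by posterior-mean parameters; state time
courses (posterior marginals "Gamma" and the Viterbi path) are decoded
from those point parameters with standard forward-backward / max-product
recursions.  Inference runs on the continuous data with no knowledge of
task structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from ._hmmcore import forward_backward, viterbi
from .envelope import ContinuousRecording

__all__ = [
    "HMMFit",
    "StateTimeCourses",
    "fit_aehmm",
    "identify_beta_state",
    "infer_state_timecourses",
]

_LOG2PI = np.log(2 * np.pi)


@dataclass
class HMMFit:
    """A fitted two-state Gaussian-observation HMM (posterior means)."""

    state_means: np.ndarray          # (K,) envelope units
    state_vars: np.ndarray           # (K,) envelope units^2
    transition_matrix: np.ndarray    # (K, K) row-stochastic
    initial_probs: np.ndarray        # (K,)
    free_energy_trace: list[np.ndarray]  # one trace per restart
    best_restart: int
    seed: int
    fs: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial_probs.sum(), 1.0, atol=1e-10):
            raise ValueError("initial state probabilities must sum to 1")
        if np.any(self.state_vars <= 0):
            raise ValueError("state variances must be positive")

    @property
    def free_energy(self) -> float:
        return float(self.free_energy_trace[self.best_restart][-1])


@dataclass
class StateTimeCourses:
    """Per-sample posterior state probabilities and Viterbi path.

    ``gamma`` columns are ordered (other, beta); ``viterbi`` is binary with
    1 marking the beta (high-amplitude) state.
    """

    gamma: np.ndarray     # (T, 2)
    viterbi: np.ndarray   # (T,) in {0, 1}
    fs: float

    def __post_init__(self) -> None:
        if self.gamma.shape[0] != self.viterbi.shape[0]:
            raise ValueError("gamma and viterbi lengths differ")
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("gamma rows must sum to 1")


def identify_beta_state(fit: HMMFit) -> int:
    """Index of the beta state: the state with the larger mean amplitude.

    Ties resolve to the lower index with a warning (degenerate fit).
    """
    means = np.asarray(fit.state_means)
    if means[0] == means[1]:
        warnings.warn("state means are tied; beta-state identity is degenerate")
        return 0
    return int(np.argmax(means))


# ---------------------------------------------------------------------------
# variational Bayes inference


def _kl_dirichlet(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    s, s0 = alpha.sum(), alpha0.sum()
    return float(
        gammaln(s)
        - gammaln(alpha).sum()
        - gammaln(s0)
        + gammaln(alpha0).sum()
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(s)))
    )


def _kl_normal_gamma(m, beta, a, b, m0, beta0, a0, b0) -> float:
    # KL( NG(m,beta,a,b) || NG(m0,beta0,a0,b0) )
    kl_gamma = (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )
    kl_normal = 0.5 * (
        np.log(beta / beta0) + beta0 / beta - 1.0 + beta0 * (a / b) * (m - m0) ** 2
    )
    return float(kl_gamma + kl_normal)


class _VBPosterior:
    """Hyperparameters of the variational posterior for a K-state fit."""

    __slots__ = ("w", "u", "m", "beta", "a", "b", "prior")

    def __init__(self, prior):
        self.prior = prior

    def m_step(self, x, gamma, xi_sum):
        p = self.prior
        self.w = p["w0"] + gamma[0]
        self.u = p["u0"] + xi_sum
        nk = gamma.sum(axis=0) + 1e-12
        xbar = gamma.T @ x / nk
        sk = (gamma * (x[:, None] - xbar[None, :]) ** 2).sum(axis=0)
        self.beta = p["beta0"] + nk
        self.m = (p["beta0"] * p["m0"] + nk * xbar) / self.beta
        self.a = p["a0"] + nk / 2.0
        self.b = p["b0"] + 0.5 * (
            sk + p["beta0"] * nk * (xbar - p["m0"]) ** 2 / self.beta
        )

    def expected_log_scores(self, x):
        log_pi = digamma(self.w) - digamma(self.w.sum())
        log_a = digamma(self.u) - digamma(self.u.sum(axis=1))[:, None]
        elog_tau = digamma(self.a) - np.log(self.b)
        e_quad = (self.a / self.b)[None, :] * (x[:, None] - self.m[None, :]) ** 2
        log_b = 0.5 * (elog_tau[None, :] - _LOG2PI) - 0.5 * (
            e_quad + (1.0 / self.beta)[None, :]
        )
        return log_b, log_pi, log_a

    def kl(self) -> float:
        p = self.prior
        total = _kl_dirichlet(self.w, p["w0"])
        for j in range(self.u.shape[0]):
            total += _kl_dirichlet(self.u[j], p["u0"][j])
        for k in range(self.m.size):
            total += _kl_normal_gamma(
                self.m[k], self.beta[k], self.a[k], self.b[k],
                p["m0"], p["beta0"], p["a0"], p["b0"],
            )
        return total


def _default_prior(x: np.ndarray, n_states: int) -> dict:
    """Weakly informative empirical prior centred on the data moments."""
    return {
        "w0": np.ones(n_states),
        "u0": np.ones((n_states, n_states)),
        "m0": float(np.mean(x)),
        "beta0": 0.01,
        "a0": 1.0,
        "b0": float(np.var(x)) + 1e-12,
    }


def _run_vb(x, prior, rng, max_iter, tol_rel):
    T = x.size
    K = prior["u0"].shape[0]
    post = _VBPosterior(prior)
    # random-responsibility initialisation, symmetry broken by anchoring each
    # state on a randomly drawn observation (iid Dirichlet responsibilities
    # leave both states at the data mean, a fixed point of the iteration)
    anchors = x[rng.choice(T, size=K, replace=False)]
    s2 = 2.0 * max(np.var(x), 1e-12)
    logits = -((x[:, None] - anchors[None, :]) ** 2) / s2
    logits += rng.gumbel(scale=0.1, size=(T, K))
    logits -= logits.max(axis=1, keepdims=True)
    gamma = np.exp(logits)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = gamma[:-1].T @ gamma[1:]
    post.m_step(x, gamma, xi_sum)

    trace = []
    prev_f = np.inf
    for _ in range(max_iter):
        log_b, log_pi, log_a = post.expected_log_scores(x)
        gamma, xi_sum, logz = forward_backward(log_b, log_pi, log_a)
        f = -logz + post.kl()
        trace.append(f)
        if abs(prev_f - f) < tol_rel * abs(f):
            break
        prev_f = f
        post.m_step(x, gamma, xi_sum)
    return post, np.asarray(trace)


def fit_aehmm(
    envelope: ContinuousRecording | np.ndarray,
    n_states: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol_rel: float = 1e-6,
    fs: float | None = None,
) -> HMMFit:
    """Fit the two-state AE-HMM by variational Bayes with restarts.

    Each restart starts from random per-sample responsibilities; the
    accepted run is the one with the lowest final free energy.  The fit is
    deterministic given the inputs and ``seed``.
    """
    if isinstance(envelope, ContinuousRecording):
        if envelope.kind != "envelope":
            raise ValueError("fit_aehmm expects an amplitude envelope")
        x = envelope.values
        fs = envelope.fs
    else:
        x = np.asarray(envelope, dtype=float)
        fs = float(fs) if fs is not None else 100.0
    if n_states != 2:
        raise ValueError("only the two-state model is supported")
    if x.size < 500:
        raise ValueError("envelope too short (need >= 500 samples)")
    scale = max(np.max(np.abs(x)), 1.0)
    if np.any(x < -1e-9 * scale):
        raise ValueError("envelope contains negative values")
    x = np.maximum(x, 0.0)

    if np.var(x) < 1e-12 * max(np.mean(x) ** 2, 1e-12):
        warnings.warn("constant envelope: degenerate fit with tied states")
        mean = float(np.mean(x))
        return HMMFit(
            state_means=np.array([mean, mean]),
            state_vars=np.array([1e-12, 1e-12]),
            transition_matrix=np.full((2, 2), 0.5),
            initial_probs=np.array([0.5, 0.5]),
            free_energy_trace=[np.array([0.0])],
            best_restart=0,
            seed=seed,
            fs=fs,
            degenerate=True,
        )

    prior = _default_prior(x, n_states)
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    traces, posts = [], []
    for child in children:
        rng = np.random.default_rng(child)
        post, trace = _run_vb(x, prior, rng, max_iter, tol_rel)
        posts.append(post)
        traces.append(trace)

    best = int(np.argmin([t[-1] for t in traces]))
    post = posts[best]
    return HMMFit(
        state_means=post.m.copy(),
        state_vars=post.b / post.a,
        transition_matrix=post.u / post.u.sum(axis=1, keepdims=True),
        initial_probs=post.w / post.w.sum(),
        free_energy_trace=traces,
        best_restart=best,
        seed=seed,
        fs=fs,
    )


def _point_log_scores(fit: HMMFit, x: np.ndarray):
    means = np.asarray(fit.state_means, dtype=float)
    var = np.asarray(fit.state_vars, dtype=float)
    log_b = -0.5 * (
        _LOG2PI + np.log(var)[None, :] + (x[:, None] - means[None, :]) ** 2 / var[None, :]
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(fit.initial_probs, 1e-300))
        log_a = np.log(np.maximum(fit.transition_matrix, 1e-300))
    return log_b, log_pi, log_a


def infer_state_timecourses(
    fit: HMMFit,
    envelope: ContinuousRecording | np.ndarray,
) -> StateTimeCourses:
    """Posterior marginals (Gamma) and Viterbi path for an envelope.

    Decoding uses the fit's posterior-mean parameters.  The returned gamma
    columns are reordered to (other, beta) and the Viterbi path is binary
    with 1 = beta state, so downstream code never needs raw state labels.
    """
    if isinstance(envelope, ContinuousRecording):
        if envelope.kind != "envelope":
            raise ValueError("expected an amplitude envelope")
        x = envelope.values
        if envelope.fs != fit.fs:
            raise ValueError("envelope sampling rate does not match the fit")
    else:
        x = np.asarray(envelope, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("envelope must be a non-empty 1-D sequence")

    log_b, log_pi, log_a = _point_log_scores(fit, x)
    gamma, _, _ = forward_backward(log_b, log_pi, log_a)
    path = viterbi(log_b, log_pi, log_a)

    beta_idx = identify_beta_state(fit)
    other_idx = 1 - beta_idx
    gamma_ordered = np.column_stack([gamma[:, other_idx], gamma[:, beta_idx]])
    return StateTimeCourses(
        gamma=gamma_ordered,
        viterbi=(path == beta_idx).astype(np.int64),
        fs=fit.fs,
    )
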