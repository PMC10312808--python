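"""Adaptive Psi staircases, Weibull fitting, and staircase quality control.

The Psi procedure is a Bayesian adaptive method: a posterior over Weibull
(alpha, beta) is updated after every trial and the next stimulus duration is
the lattice value minimizing the expected posterior entropy across the two
possible outcomes (Kontsevich & Tyler style).  Thresholds are read out by
maximum-likelihood Weibull fits with fixed guess and lapse rates, inverted
at 80% correct.  The quality-control rule flags "rising" staircases whose
late running estimates fail to drop below 0.8x the early estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_GAMMA",
    "DEFAULT_LAPSE",
    "STIM_RANGE_MS",
    "WeibullParams",
    "PsiState",
    "Trial",
    "StaircaseRecord",
    "ThresholdEstimate",
    "WeibullFit",
    "StaircaseQC",
    "MissingConditionError",
    "weibull_p_correct",
    "invert_weibull_threshold",
    "psi_update",
    "psi_select_stimulus",
    "run_staircase",
    "fit_weibull_ml",
    "staircase_qc",
    "subject_qc",
    "final_threshold",
]

DEFAULT_GAMMA = 0.5
DEFAULT_LAPSE = 0.04
#: Admissible stimulus durations (ms).
STIM_RANGE_MS = (6.7, 333.0)
QC_RATIO_THRESHOLD = 0.8
SUBJECT_FLAG_LIMIT = 4


class MissingConditionError(ValueError):
    """No surviving threshold estimates for a condition."""


@dataclass(frozen=True)
class WeibullParams:
    """Weibull psychometric parameters: p = gamma + (1-gamma-lam)(1-e^-(x/alpha)^beta)."""

    alpha: float
    beta: float
    gamma: float = DEFAULT_GAMMA
    lam: float = DEFAULT_LAPSE

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 <= self.gamma < 1 - self.lam):
            raise ValueError("need 0 <= gamma < 1 - lam")
        if not (0 <= self.lam < 1):
            raise ValueError("lam must lie in [0, 1)")


def weibull_p_correct(x, p: WeibullParams):
    """Probability correct at duration ``x`` (ms).  Vectorized in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("durations must be nonnegative")
    out = p.gamma + (1 - p.gamma - p.lam) * (1 - np.exp(-((x / p.alpha) ** p.beta)))
    return float(out) if out.ndim == 0 else out


def invert_weibull_threshold(p: WeibullParams, criterion: float = 0.80) -> float:
    """Duration (ms) at which ``weibull_p_correct`` equals ``criterion``."""
    if not (p.gamma < criterion < 1 - p.lam):
        raise ValueError(
            f"criterion {criterion} outside the attainable range "
            f"({p.gamma}, {1 - p.lam})"
        )
    frac = (criterion - p.gamma) / (1 - p.gamma - p.lam)
    return p.alpha * (-math.log1p(-frac)) ** (1.0 / p.beta)


# ---------------------------------------------------------------------------
# Psi adaptive procedure
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _likelihood_table(
    lattice: tuple, alphas: tuple, betas: tuple, gamma: float, lam: float
) -> np.ndarray:
    """p(correct | x, alpha, beta) with shape (lattice, alpha, beta)."""
    x = np.asarray(lattice)[:, None, None]
    a = np.asarray(alphas)[None, :, None]
    b = np.asarray(betas)[None, None, :]
    return gamma + (1 - gamma - lam) * (1 - np.exp(-((x / a) ** b)))


@dataclass(frozen=True)
class PsiState:
    """Posterior over (alpha, beta) plus the admissible stimulus lattice."""

    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    posterior: np.ndarray  # (n_alpha, n_beta), sums to 1
    stimulus_lattice: np.ndarray
    gamma: float = DEFAULT_GAMMA
    lam: float = DEFAULT_LAPSE

    def __post_init__(self) -> None:
        post = np.asarray(self.posterior, dtype=float)
        if np.any(post < 0) or abs(post.sum() - 1.0) > 1e-12:
            raise ValueError("posterior must be nonnegative and sum to 1")
        lat = np.asarray(self.stimulus_lattice, dtype=float)
        if lat.min() < STIM_RANGE_MS[0] - 1e-9 or lat.max() > STIM_RANGE_MS[1] + 1e-9:
            raise ValueError(f"stimulus lattice must lie within {STIM_RANGE_MS} ms")

    @classmethod
    def uniform(
        cls,
        n_alpha: int = 41,
        n_beta: int = 21,
        alpha_range: tuple[float, float] = STIM_RANGE_MS,
        beta_range: tuple[float, float] = (0.5, 16.0),
        gamma: float = DEFAULT_GAMMA,
        lam: float = DEFAULT_LAPSE,
        alpha_spacing: str = "linear",
    ) -> "PsiState":
        """Uniform prior over an alpha x log-spaced beta grid.

        The alpha grid is linear-spaced by default (Palamedes-style): its
        long upper tail starts the running threshold estimate high, so that
        converging staircases descend -- the phenotype the staircase-quality
        ratio rule assumes.  The stimulus lattice coincides with the alpha
        grid.
        """
        if alpha_spacing == "linear":
            alphas = np.linspace(*alpha_range, n_alpha)
        elif alpha_spacing == "log":
            alphas = np.geomspace(*alpha_range, n_alpha)
        else:
            raise ValueError("alpha_spacing must be 'linear' or 'log'")
        betas = np.geomspace(*beta_range, n_beta)
        post = np.full((n_alpha, n_beta), 1.0 / (n_alpha * n_beta))
        return cls(alphas, betas, post, alphas.copy(), gamma, lam)

    def _table(self) -> np.ndarray:
        return _likelihood_table(
            tuple(self.stimulus_lattice),
            tuple(self.alpha_grid),
            tuple(self.beta_grid),
            self.gamma,
            self.lam,
        )

    def lattice_index(self, x: float) -> int:
        idx = int(np.argmin(np.abs(self.stimulus_lattice - x)))
        if abs(self.stimulus_lattice[idx] - x) > 1e-6 * max(1.0, x):
            raise ValueError(f"duration {x} ms is not on the stimulus lattice")
        return idx

    def mean_alpha_ms(self) -> float:
        """Posterior mean of alpha -- the running threshold estimate."""
        marg = self.posterior.sum(axis=1)
        return float(self.alpha_grid @ marg)


def psi_update(state: PsiState, x: float, correct: bool) -> PsiState:
    """Bayes update of the posterior after observing (x, correct)."""
    like = state._table()[state.lattice_index(x)]
    if not correct:
        like = 1.0 - like
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise ValueError("posterior mass vanished during update")
    return replace(state, posterior=post / total)


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-300, 1.0)
    q = np.clip(1.0 - p, 1e-300, 1.0)
    return -(p * np.log(p) + q * np.log(q))


@lru_cache(maxsize=8)
def _binary_entropy_table(
    lattice: tuple, alphas: tuple, betas: tuple, gamma: float, lam: float
) -> np.ndarray:
    return _binary_entropy(_likelihood_table(lattice, alphas, betas, gamma, lam))


def expected_posterior_entropy(state: PsiState) -> np.ndarray:
    """Expected entropy of the updated posterior for each lattice duration.

    Uses the identity E_outcome[H(post')] = H(post) - H(outcome) +
    E_theta[h(P)], with h the binary entropy, which avoids forming the two
    candidate posteriors explicitly.
    """
    key = (
        tuple(state.stimulus_lattice),
        tuple(state.alpha_grid),
        tuple(state.beta_grid),
        state.gamma,
        state.lam,
    )
    P = _likelihood_table(*key).reshape(len(state.stimulus_lattice), -1)
    hP = _binary_entropy_table(*key).reshape(len(state.stimulus_lattice), -1)
    post = state.posterior.ravel()
    p_mean = P @ post
    cond_ent = hP @ post
    h_current = float(-(post * np.log(np.clip(post, 1e-300, 1.0))).sum())
    return h_current - _binary_entropy(p_mean) + cond_ent


def psi_select_stimulus(state: PsiState) -> float:
    """Lattice duration minimizing expected posterior entropy; ties -> shorter."""
    expected = expected_posterior_entropy(state)
    best = expected.min()
    candidates = np.flatnonzero(expected <= best + 1e-12)
    return float(state.stimulus_lattice[candidates].min())


# ---------------------------------------------------------------------------
# Staircase simulation and records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    duration_ms: float
    correct: bool
    running_estimate_ms: float


@dataclass(frozen=True)
class StaircaseRecord:
    """One adaptive staircase: ordered trials with running threshold estimates."""

    condition: str
    trials: tuple[Trial, ...]
    subject_id: str = ""
    run: int = 0

    @property
    def durations(self) -> np.ndarray:
        return np.array([t.duration_ms for t in self.trials])

    @property
    def responses(self) -> np.ndarray:
        return np.array([t.correct for t in self.trials], dtype=bool)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([t.running_estimate_ms for t in self.trials])


@dataclass(frozen=True)
class ThresholdEstimate:
    condition: str
    per_run: tuple[float, ...]
    final: float


def run_staircase(
    observer: WeibullParams,
    n_trials: int = 25,
    rng: np.random.Generator | int | None = None,
    condition: str = "",
    subject_id: str = "",
    run: int = 0,
    state: PsiState | None = None,
    response_fn: Callable[[int, float, np.random.Generator], bool] | None = None,
) -> StaircaseRecord:
    """Simulate one Psi staircase against a Weibull observer.

    ``response_fn`` overrides the observer's response generation (used to
    model inattentive behavior); by default responses are Bernoulli draws
    from the observer's full psychometric function, lapses included.
    """
    rng = np.random.default_rng(rng)
    if state is None:
        state = PsiState.uniform(gamma=observer.gamma, lam=observer.lam)
    trials = []
    for i in range(n_trials):
        x = psi_select_stimulus(state)
        if response_fn is not None:
            correct = bool(response_fn(i, x, rng))
        else:
            correct = bool(rng.random() < weibull_p_correct(x, observer))
        state = psi_update(state, x, correct)
        trials.append(Trial(x, correct, state.mean_alpha_ms()))
    return StaircaseRecord(condition, tuple(trials), subject_id, run)


# ---------------------------------------------------------------------------
# Weibull maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullFit:
    params: WeibullParams
    threshold_ms: float
    status: str  # "ok" | "boundary"


ALPHA_BOUNDS = (1.0, 1000.0)
BETA_BOUNDS = (0.5, 16.0)


def _grid_nll(x, k, la, lb, gamma, lam):
    """Negative log-likelihood over a log-alpha x log-beta grid."""
    p = gamma + (1 - gamma - lam) * (
        1 - np.exp(-np.exp(np.exp(lb)[None, None, :] * (np.log(x)[:, None, None] - la[None, :, None])))
    )
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(np.log(p)[k].sum(axis=0) + np.log1p(-p)[~k].sum(axis=0))


def fit_weibull_ml(
    record: StaircaseRecord | tuple[np.ndarray, np.ndarray],
    gamma: float = DEFAULT_GAMMA,
    lam: float = DEFAULT_LAPSE,
    criterion: float = 0.80,
) -> WeibullFit:
    """Maximum-likelihood (alpha, beta) with fixed gamma/lam; returns the
    fitted parameters and the inverted threshold at ``criterion``.

    Alpha is searched in log space over [1, 1000] ms and beta over
    [0.5, 16].  Records with all-correct or all-incorrect responses produce
    a boundary fit flagged via ``status``.
    """
    if isinstance(record, StaircaseRecord):
        x, k = record.durations, record.responses
    else:
        x, k = np.asarray(record[0], float), np.asarray(record[1], bool)
    if x.size < 10:
        raise ValueError("need at least 10 trials to fit")
    # deterministic two-stage grid search in (log alpha, log beta)
    la = np.log(np.geomspace(*ALPHA_BOUNDS, 61))
    lb = np.log(np.geomspace(*BETA_BOUNDS, 31))
    for _ in range(3):
        nll = _grid_nll(x, k, la, lb, gamma, lam)
        i0, j0 = np.unravel_index(np.argmin(nll), nll.shape)
        da = la[1] - la[0]
        db = lb[1] - lb[0]
        la = np.clip(np.linspace(la[i0] - da, la[i0] + da, 17), *np.log(ALPHA_BOUNDS))
        lb = np.clip(np.linspace(lb[j0] - db, lb[j0] + db, 13), *np.log(BETA_BOUNDS))
    nll = _grid_nll(x, k, la, lb, gamma, lam)
    i0, j0 = np.unravel_index(np.argmin(nll), nll.shape)
    alpha, beta = float(np.exp(la[i0])), float(np.exp(lb[j0]))
    status = "ok"
    if k.all() or (~k).all():
        status = "boundary"
    else:
        tol = 1e-6
        at_bound = (
            alpha <= ALPHA_BOUNDS[0] * (1 + tol)
            or alpha >= ALPHA_BOUNDS[1] * (1 - tol)
            or beta <= BETA_BOUNDS[0] * (1 + tol)
            or beta >= BETA_BOUNDS[1] * (1 - tol)
        )
        if at_bound:
            status = "boundary"
    params = WeibullParams(alpha, beta, gamma, lam)
    return WeibullFit(params, invert_weibull_threshold(params, criterion), status)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseQC:
    ratio: float
    flagged: bool
    late_spike: bool  # supplementary deterministic rule, logged separately


def staircase_qc(
    record: StaircaseRecord, ratio_threshold: float = QC_RATIO_THRESHOLD
) -> StaircaseQC:
    """Rising-staircase detection: mean(last 5 estimates)/mean(first 10) > 0.8.

    A supplementary rule (``late_spike``) additionally marks staircases whose
    maximum running estimate occurs after trial 15 and exceeds twice the
    first-10 mean; it stands in for the visual-inspection step and is
    reported separately from the ratio rule.
    """
    est = record.estimates
    if est.size < 15:
        raise ValueError("staircase QC needs at least 15 trials")
    first10 = float(est[:10].mean())
    last5 = float(est[-5:].mean())
    if first10 == 0:
        raise ValueError("zero mean over the first 10 estimates")
    ratio = last5 / first10
    peak_idx = int(np.argmax(est))
    late_spike = bool(peak_idx >= 15 and est[peak_idx] > 2.0 * first10)
    return StaircaseQC(ratio, ratio > ratio_threshold, late_spike)


def subject_qc(
    records: Sequence[StaircaseRecord], flag_limit: int = SUBJECT_FLAG_LIMIT
) -> tuple[int, bool]:
    """Count ratio-rule flags; a subject with >= 4 is an exclusion candidate."""
    n_flagged = sum(staircase_qc(r).flagged for r in records)
    return n_flagged, n_flagged >= flag_limit


def final_threshold(per_run: Sequence[float]) -> float:
    """Median of the surviving per-run threshold estimates."""
    vals = [float(v) for v in per_run]
    if not vals:
        raise MissingConditionError("no surviving threshold estimates")
    return float(np.median(vals))
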