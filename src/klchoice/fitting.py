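"""Constrained maximum-likelihood estimation of preferences and precision.

For each subject and model variant, the free parameters are the utilities
of outcomes 2..K (outcome 1 is pinned at 0 to remove the softmax shift
degeneracy) and, when estimated, the shape alpha of the gamma precision
prior (rate fixed at 1, so the softmax inverse temperature is alpha
itself).  Boxes: alpha in [2, 8], utilities in [-10, 10]; estimates on the
boundary are returned as-is.

The likelihood of a trial's choice is the softmax probability of the
chosen side.  Because the log-preference normalizer is shared by both
options, the value difference reduces to an affine function of the
utilities::

    V(left) - V(right) = [ln k_L - ln k_R] * (KL only) + A_t · u

where ``A_t`` holds the signed membership weights ``1/k_L`` minus
``1/k_R`` per outcome.  The negative log-likelihood and its gradient are
evaluated on this vectorized form; a unit test cross-checks it against
trial-by-trial evaluation through the core choice rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .comparison import bic_score
from .core import (
    DEFAULT_UNIVERSE_SIZE,
    ModelSpec,
    PrecisionMode,
    TrialOffer,
    UtilityProfile,
    Valuation,
)

__all__ = [
    "SubjectFit",
    "TrialMatrix",
    "negative_log_likelihood",
    "fit_subject",
    "rating_correlation",
    "ALPHA_BOUNDS",
    "UTILITY_BOUNDS",
    "FIXED_ALPHA",
]

ALPHA_BOUNDS = (2.0, 8.0)
UTILITY_BOUNDS = (-10.0, 10.0)
FIXED_ALPHA = 4.0


@dataclass(frozen=True)
class SubjectFit:
    """Fitted parameters and evidence for one subject under one model."""

    subject_id: Optional[int]
    spec: ModelSpec
    alpha_hat: float
    utilities_hat: UtilityProfile
    log_likelihood: float
    n_params: int
    bic_score: float
    n_trials: int
    rating_correlation: Optional[float] = None

    @property
    def precision(self) -> float:
        return self.alpha_hat  # beta = 1 throughout


@dataclass(frozen=True)
class TrialMatrix:
    """Precomputed design quantities for fast likelihood evaluation."""

    membership: np.ndarray  # (n_trials, universe) signed 1/k weights, left - right
    d_log_k: np.ndarray  # (n_trials,) ln k_left - ln k_right
    choices: np.ndarray  # (n_trials,) +1 left / -1 right
    universe_size: int

    @classmethod
    def build(
        cls,
        trials: Sequence[TrialOffer],
        choices: pd.DataFrame | np.ndarray,
        universe_size: int = DEFAULT_UNIVERSE_SIZE,
    ) -> "TrialMatrix":
        if isinstance(choices, pd.DataFrame):
            by_id = choices.set_index("trial_id")["choice"]
            c = np.array([by_id[t.trial_id] for t in trials], dtype=float)
        else:
            c = np.asarray(choices, dtype=float)
        if not np.all(np.isin(c, (-1.0, 1.0))):
            raise ValueError("choices must be coded +1 (left) / -1 (right)")
        n = len(trials)
        a = np.zeros((n, universe_size))
        dlnk = np.zeros(n)
        for i, t in enumerate(trials):
            for o in t.left.outcome_ids:
                a[i, o - 1] += 1.0 / t.left.cardinality
            for o in t.right.outcome_ids:
                a[i, o - 1] -= 1.0 / t.right.cardinality
            dlnk[i] = math.log(t.left.cardinality) - math.log(t.right.cardinality)
        return cls(membership=a, d_log_k=dlnk, choices=c, universe_size=universe_size)

    @property
    def n_trials(self) -> int:
        return self.choices.size


def _value_difference(matrix: TrialMatrix, u: np.ndarray, valuation: Valuation) -> np.ndarray:
    dv = matrix.membership @ u
    if valuation is Valuation.KL_CONTROL:
        dv = dv + matrix.d_log_k
    return dv


def _check_box(alpha: float, u_free: np.ndarray) -> None:
    eps = 1e-9
    if not (ALPHA_BOUNDS[0] - eps <= alpha <= ALPHA_BOUNDS[1] + eps):
        raise ValueError(f"alpha {alpha} outside box {ALPHA_BOUNDS}")
    if np.any(u_free < UTILITY_BOUNDS[0] - eps) or np.any(u_free > UTILITY_BOUNDS[1] + eps):
        raise ValueError(f"utilities outside box {UTILITY_BOUNDS}")


def negative_log_likelihood(
    params: np.ndarray,
    matrix: TrialMatrix,
    spec: ModelSpec,
) -> float:
    """-sum_t ln P(choice_t) for params = [alpha, u_2, ..., u_K].

    The fixed-precision variant ignores the supplied alpha and uses 4.
    Parameters outside the constraint box raise.
    """
    params = np.asarray(params, dtype=float)
    alpha, u_free = float(params[0]), params[1:]
    if spec.precision_mode is PrecisionMode.FIXED:
        alpha = FIXED_ALPHA
    _check_box(alpha, u_free)
    u = np.concatenate(([0.0], u_free))
    dv = _value_difference(matrix, u, spec.valuation)
    z = alpha * matrix.choices * dv
    return float(np.sum(np.logaddexp(0.0, -z)))


def _nll_and_grad(
    x: np.ndarray, matrix: TrialMatrix, spec: ModelSpec
) -> Tuple[float, np.ndarray]:
    """Objective for the optimizer over the free-parameter vector only."""
    estimated = spec.precision_mode is PrecisionMode.ESTIMATED
    if estimated:
        alpha, u_free = float(x[0]), x[1:]
    else:
        alpha, u_free = FIXED_ALPHA, x
    u = np.concatenate(([0.0], u_free))
    dv = _value_difference(matrix, u, spec.valuation)
    z = alpha * matrix.choices * dv
    nll = float(np.sum(np.logaddexp(0.0, -z)))
    # d/dz log(1+e^{-z}) = -sigma(-z)
    s = -expit(-z)
    dz_du = alpha * matrix.choices[:, None] * matrix.membership[:, 1:]
    grad_u = dz_du.T @ s
    if estimated:
        grad_alpha = float(s @ (matrix.choices * dv))
        return nll, np.concatenate(([grad_alpha], grad_u))
    return nll, grad_u


class FitError(RuntimeError):
    """All optimizer restarts failed; carries the best partial result."""

    def __init__(self, message: str, best: Optional[SubjectFit] = None):
        super().__init__(message)
        self.best = best


def fit_subject(
    trials: Sequence[TrialOffer],
    choices: pd.DataFrame | np.ndarray,
    spec: ModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    subject_id: Optional[int] = None,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    tol: float = 1e-6,
) -> SubjectFit:
    """Box-constrained ML fit from multiple random interior starts.

    Runs L-BFGS-B from ``n_restarts`` starts drawn uniformly inside the
    box (deterministic under ``seed``) and returns the best optimum.  The
    BIC free-parameter count includes alpha only when it is estimated.
    """
    matrix = TrialMatrix.build(trials, choices, universe_size)
    if matrix.n_trials < 30:
        warnings.warn(
            f"only {matrix.n_trials} trials; estimates may be unstable", RuntimeWarning
        )
    estimated = spec.precision_mode is PrecisionMode.ESTIMATED
    n_free_u = universe_size - 1
    bounds = ([ALPHA_BOUNDS] if estimated else []) + [UTILITY_BOUNDS] * n_free_u

    rng = np.random.default_rng(seed)
    best = None
    failures = []
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(matrix, spec),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all {n_restarts} restarts failed: {failures}")

    x = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    if estimated:
        alpha_hat, u_free = float(x[0]), x[1:]
    else:
        alpha_hat, u_free = FIXED_ALPHA, x
    n_params = n_free_u + (1 if estimated else 0)
    ll = -float(best.fun)
    return SubjectFit(
        subject_id=subject_id,
        spec=spec,
        alpha_hat=alpha_hat,
        utilities_hat=UtilityProfile.from_vector(np.concatenate(([0.0], u_free))),
        log_likelihood=ll,
        n_params=n_params,
        bic_score=bic_score(ll, n_params, matrix.n_trials),
        n_trials=matrix.n_trials,
    )


def rating_correlation(fit: SubjectFit, ratings: pd.DataFrame) -> float:
    """Pearson correlation of fitted utilities with mean explicit ratings.

    Ratings must cover all outcomes in the fitted universe.  Returns NaN
    (with a warning) if either vector has zero variance.
    """
    mean_ratings = ratings.groupby("outcome_id")["rating"].mean()
    universe = fit.utilities_hat.universe
    missing = [o for o in universe if o not in mean_ratings.index]
    if missing:
        raise ValueError(f"ratings missing for outcomes {missing}")
    u = np.array([fit.utilities_hat[o] for o in universe])
    r = mean_ratings.loc[list(universe)].to_numpy()
    if np.std(u) == 0 or np.std(r) == 0:
        warnings.warn("zero variance; correlation undefined", RuntimeWarning)
        return float("nan")
    return float(stats.pearsonr(u, r)[0])
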