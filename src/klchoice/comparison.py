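"""Model evidence and random-effects Bayesian model selection.

Per-subject model evidence is approximated by a BIC score in log-evidence
orientation, ``LL - (k/2) ln n`` (higher is better; the classical
``-2 LL + k ln n`` is minus twice this).  Group-level selection treats the
generating model as a subject-level random variable with Dirichlet-
distributed population frequencies and runs the standard variational
fixed-point scheme: subject responsibilities are softmaxed log evidences
corrected by the digamma of the Dirichlet counts, and the counts are the
prior plus the summed responsibilities.  The headline summary is the
exceedance probability — the posterior probability that a model is the
most frequent in the population — computed exactly through the Beta
distribution for two models and by seeded Dirichlet Monte Carlo for more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, logsumexp

__all__ = [
    "EvidenceMatrix",
    "BmsResult",
    "bic_score",
    "random_effects_bms",
    "exceedance_from_dirichlet",
    "reproduce_table_comparison",
]


def bic_score(log_likelihood: float, n_params: int, n_obs: int) -> float:
    """Log-evidence-oriented BIC: ``LL - (n_params / 2) * ln(n_obs)``.

    Higher is better; the penalty grows with the free-parameter count.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return float(log_likelihood) - 0.5 * n_params * math.log(n_obs)


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models table of log-evidence approximations."""

    values: np.ndarray  # (n_subjects, n_models)
    model_names: tuple

    def __init__(self, values, model_names: Sequence[str]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("evidence matrix must be 2-D (subjects x models)")
        if arr.shape[1] < 2:
            raise ValueError("need at least two models")
        if arr.shape[0] < 2:
            raise ValueError("need at least two subjects for random effects")
        if not np.all(np.isfinite(arr)):
            raise ValueError("evidence matrix contains missing/non-finite entries")
        if arr.shape[1] != len(model_names):
            raise ValueError("model_names length must match the number of columns")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "model_names", tuple(model_names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EvidenceMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.columns))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BmsResult:
    """Posterior of the random-effects model-selection scheme."""

    dirichlet_alpha: np.ndarray
    expected_probabilities: np.ndarray
    exceedance_probabilities: np.ndarray
    model_names: tuple
    n_iterations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_probability": self.expected_probabilities,
                "exceedance_probability": self.exceedance_probabilities,
            }
        )


class BmsConvergenceError(RuntimeError):
    """Variational scheme failed to converge within the iteration cap."""


def exceedance_from_dirichlet(
    alpha: np.ndarray, seed: Optional[int] = None, n_mc: int = 1_000_000
) -> np.ndarray:
    """P(model k has the largest population frequency) under Dirichlet(alpha).

    Exact via the Beta marginal for two models (frequency of model 2 is
    Beta(alpha2, alpha1), and exceeding 1/2 is exceeding the other model);
    Monte Carlo over seeded Dirichlet draws otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.size
    if k == 2:
        phi2 = float(stats.beta.sf(0.5, alpha[1], alpha[0]))
        return np.array([1.0 - phi2, phi2])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_mc))
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=k) / float(n_mc)


def random_effects_bms(
    evidence: EvidenceMatrix | pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    seed: Optional[int] = None,
    n_mc: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    model_names: Optional[Sequence[str]] = None,
) -> BmsResult:
    """Variational Dirichlet model selection over subjects.

    Iterates responsibilities ``u_nk ∝ exp(L_nk + ψ(α_k) - ψ(Σ α))``
    (normalized per subject) and counts ``α_k = alpha0 + Σ_n u_nk`` until
    the change in α drops below ``tol``.
    """
    if isinstance(evidence, pd.DataFrame):
        evidence = EvidenceMatrix.from_frame(evidence)
    elif isinstance(evidence, np.ndarray):
        names = model_names or [f"model_{i + 1}" for i in range(evidence.shape[1])]
        evidence = EvidenceMatrix(evidence, names)

    log_ev = evidence.values
    n, k = log_ev.shape
    alpha = np.full(k, float(alpha0))
    for iteration in range(1, max_iter + 1):
        log_u = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise BmsConvergenceError(
            f"no convergence after {max_iter} iterations; last alpha = {alpha}"
        )

    expected = alpha / alpha.sum()
    exceedance = exceedance_from_dirichlet(alpha, seed=seed, n_mc=n_mc)
    return BmsResult(
        dirichlet_alpha=alpha,
        expected_probabilities=expected,
        exceedance_probabilities=exceedance,
        model_names=evidence.model_names,
        n_iterations=iteration,
    )


def reproduce_table_comparison(
    fixture_name: str,
    alpha0: float = 1.0,
    seed: Optional[int] = None,
    n_mc: int = 1_000_000,
):
    """Run the group BMS on a packaged evidence table (table2 or table3).

    Returns ``(BmsResult, column_sums)`` where the sums are the per-model
    totals of the subject-level scores.
    """
    from .fixtures import load_fixture

    if fixture_name not in {"table2", "table3"}:
        raise ValueError("model-comparison fixtures are 'table2' and 'table3'")
    table = load_fixture(fixture_name)
    frame = table.frame.drop(columns=["subject"])
    result = random_effects_bms(frame, alpha0=alpha0, seed=seed, n_mc=n_mc)
    sums = frame.sum(axis=0)
    return result, sums
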