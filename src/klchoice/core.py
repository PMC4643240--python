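"""Valuation and choice mathematics for binary lottery decisions.

A trial offers two options, each a uniform lottery over 1-4 distinct
outcomes drawn from a small outcome universe (6 snacks or colors in the
studies this package emulates).  Two families of agents are modelled:

* **KL-control** (surprise minimization): the value of an option is the
  negative Kullback-Leibler divergence between the outcome distribution the
  option induces and the agent's preferred outcome distribution.  This
  decomposes into an entropy bonus plus expected log-preference, so such
  agents "keep their options open" in addition to seeking utility.
* **Expected utility**: the same value with the entropy term switched off,
  so option rankings reduce to classical expected utility.

Choices follow a softmax over the two option values, scaled by a precision
(inverse temperature) given by the mean of a gamma prior.  In a one-shot
task the precision is never updated, so only the prior mean matters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "Option",
    "TrialOffer",
    "UtilityProfile",
    "PrecisionPrior",
    "Valuation",
    "PrecisionMode",
    "ModelSpec",
    "outcome_distribution",
    "entropy_gain",
    "expected_utility",
    "risk",
    "preference_prior",
    "kl_value",
    "eu_value",
    "option_value",
    "choice_probabilities",
    "DEFAULT_UNIVERSE_SIZE",
]

#: Both studies used six items (snacks / colors) per session.
DEFAULT_UNIVERSE_SIZE = 6


class MalformedTrialError(ValueError):
    """Raised when an option or trial violates the task's design invariants."""


@dataclass(frozen=True)
class Option:
    """A uniform lottery over a set of distinct outcome identities.

    Parameters
    ----------
    outcome_ids
        Outcome identifiers (1-based), unique within the option.  The
        implied outcome distribution is uniform: each listed outcome has
        probability ``1/k`` where ``k = len(outcome_ids)``.
    """

    outcome_ids: Tuple[int, ...]

    def __init__(self, outcome_ids: Iterable[int]):
        ids = tuple(int(i) for i in outcome_ids)
        if len(ids) == 0:
            raise MalformedTrialError("option must contain at least one outcome")
        if len(set(ids)) != len(ids):
            raise MalformedTrialError(f"duplicate outcomes in option: {ids}")
        object.__setattr__(self, "outcome_ids", tuple(sorted(ids)))

    @property
    def cardinality(self) -> int:
        return len(self.outcome_ids)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.outcome_ids)


@dataclass(frozen=True)
class TrialOffer:
    """One binary choice trial: a left and a right option."""

    trial_id: int
    left: Option
    right: Option


@dataclass(frozen=True)
class UtilityProfile:
    """Per-outcome utilities over the session's outcome universe.

    Utilities are dimensionless.  When produced by fitting, the reference
    outcome (id 1) is pinned to 0 and the others lie in [-10, 10].
    """

    utilities: Mapping[int, float]

    def __init__(self, utilities: Mapping[int, float]):
        object.__setattr__(
            self, "utilities", {int(k): float(v) for k, v in utilities.items()}
        )

    @classmethod
    def from_vector(cls, values: Sequence[float]) -> "UtilityProfile":
        """Build a profile from a vector indexed by outcome id 1..K."""
        return cls({i + 1: float(v) for i, v in enumerate(values)})

    def vector(self, universe_size: int = DEFAULT_UNIVERSE_SIZE) -> np.ndarray:
        """Utilities as a dense vector for outcomes 1..universe_size."""
        try:
            return np.array(
                [self.utilities[i] for i in range(1, universe_size + 1)], dtype=float
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no utility for outcome {exc.args[0]}") from exc

    def __getitem__(self, outcome_id: int) -> float:
        try:
            return self.utilities[outcome_id]
        except KeyError:
            raise KeyError(f"no utility defined for outcome {outcome_id}")

    @property
    def universe(self) -> Tuple[int, ...]:
        return tuple(sorted(self.utilities))


@dataclass(frozen=True)
class PrecisionPrior:
    """Gamma prior over choice precision; shape ``alpha``, rate ``beta``.

    The softmax inverse temperature is the prior mean ``gamma = alpha/beta``.
    ``beta`` is fixed at 1 throughout; ``alpha`` is either estimated in
    [2, 8] or fixed at 4.
    """

    alpha: float
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma prior parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


class Valuation(str, enum.Enum):
    KL_CONTROL = "kl"
    EXPECTED_UTILITY = "eu"


class PrecisionMode(str, enum.Enum):
    ESTIMATED = "estimated"
    FIXED = "fixed"


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model variants: {KL, EU} x {estimated, fixed} precision."""

    valuation: Valuation = Valuation.KL_CONTROL
    precision_mode: PrecisionMode = PrecisionMode.ESTIMATED

    @property
    def name(self) -> str:
        return f"{self.valuation.value}_{self.precision_mode.value}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def outcome_distribution(
    option: Option, universe_size: int = DEFAULT_UNIVERSE_SIZE
) -> np.ndarray:
    """Probability vector over outcomes 1..universe_size induced by an option.

    Each listed outcome has probability 1/k; all others 0.
    """
    k = option.cardinality
    if k > universe_size:
        raise MalformedTrialError(
            f"option has {k} outcomes but universe has only {universe_size}"
        )
    if max(option.outcome_ids) > universe_size or min(option.outcome_ids) < 1:
        raise MalformedTrialError(
            f"outcome ids {option.outcome_ids} outside universe 1..{universe_size}"
        )
    q = np.zeros(universe_size)
    q[[i - 1 for i in option.outcome_ids]] = 1.0 / k
    return q


def entropy_gain(option: Option) -> float:
    """Shannon entropy (nats) of the option's outcome lottery: ln k."""
    return math.log(option.cardinality)


def expected_utility(option: Option, profile: UtilityProfile) -> float:
    """Probability-weighted mean utility: (1/k) * sum of listed utilities."""
    return float(np.mean([profile[i] for i in option.outcome_ids]))


def risk(option: Option, profile: UtilityProfile) -> float:
    """Population variance of the option's outcome utilities under 1/k weights."""
    u = np.array([profile[i] for i in option.outcome_ids], dtype=float)
    return float(np.mean((u - u.mean()) ** 2))


def preference_prior(
    profile: UtilityProfile, universe_size: int = DEFAULT_UNIVERSE_SIZE
) -> np.ndarray:
    """Preferred outcome distribution C(o) = softmax of utilities.

    C(o) = exp(u(o)) / sum_o' exp(u(o')), strictly positive, sums to 1 and
    invariant to shifting all utilities by a constant.
    """
    u = profile.vector(universe_size)
    z = u - u.max()  # overflow guard
    e = np.exp(z)
    return e / e.sum()


def kl_value(
    option: Option,
    profile: UtilityProfile,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> float:
    """KL-control value: -D_KL[Q(o|option) || C(o)].

    Equals entropy_gain(option) + sum_o Q(o) ln C(o); terms with Q(o)=0
    contribute nothing (0 ln 0 = 0 convention).  C is strictly positive by
    construction so the divergence is always finite.
    """
    q = outcome_distribution(option, universe_size)
    log_c = np.log(preference_prior(profile, universe_size))
    support = q > 0
    return float(entropy_gain(option) + q[support] @ log_c[support])


def eu_value(
    option: Option,
    profile: UtilityProfile,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> float:
    """Expected-utility value: sum_o Q(o) ln C(o) (entropy term switched off).

    Equals expected_utility(option) - ln sum exp(u); the additive constant is
    shared by both options of a trial, so rankings match expected utility.
    """
    q = outcome_distribution(option, universe_size)
    log_c = np.log(preference_prior(profile, universe_size))
    support = q > 0
    return float(q[support] @ log_c[support])


def option_value(
    option: Option,
    profile: UtilityProfile,
    valuation: Valuation,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> float:
    """Dispatch to the KL-control or expected-utility value."""
    if valuation is Valuation.KL_CONTROL:
        return kl_value(option, profile, universe_size)
    return eu_value(option, profile, universe_size)


def choice_probabilities(
    trial: TrialOffer,
    profile: UtilityProfile,
    prior: PrecisionPrior,
    spec: ModelSpec,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> Tuple[float, float]:
    """Softmax choice probabilities (P(left), P(right)).

    P(left) = sigma(gamma * (V(left) - V(right))) with gamma the precision
    prior's mean and V the model's option value.
    """
    gamma = prior.mean
    v_left = option_value(trial.left, profile, spec.valuation, universe_size)
    v_right = option_value(trial.right, profile, spec.valuation, universe_size)
    d = gamma * (v_left - v_right)
    p_left = float(1.0 / (1.0 + np.exp(-d)))
    return p_left, 1.0 - p_left
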