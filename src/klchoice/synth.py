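"""Synthetic study designs and simulated agents.

Emulates the behavioral design: 300 main-task trials per subject (three
sessions of 100), half constructed so the two options have similar expected
utility but different entropy; a 180-trial color control task whose first
50 trials are training; and explicit outcome ratings (each outcome rated
three times).  Agents are parameterized by a utility profile, a gamma prior
over precision, and a valuation family, and choose via the softmax rule in
:mod:`klchoice.core`.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_UNIVERSE_SIZE,
    ModelSpec,
    Option,
    PrecisionPrior,
    TrialOffer,
    UtilityProfile,
    choice_probabilities,
    entropy_gain,
    expected_utility,
)

__all__ = [
    "AgentSpec",
    "DesignSpec",
    "generate_design",
    "is_matched_trial",
    "simulate_choices",
    "generate_color_design",
    "emit_ratings",
    "random_agent",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
]


@dataclass(frozen=True)
class AgentSpec:
    """A generative agent standing in for one subject.

    Utilities respect the fitting box ([-10, 10] with outcome 1 at 0) so
    recovered parameters are directly comparable to the fitted ones.
    """

    utilities: UtilityProfile
    precision_prior: PrecisionPrior
    model: ModelSpec = field(default_factory=ModelSpec)
    rating_noise_sd: float = 0.5

    def __post_init__(self):
        u = self.utilities.vector(len(self.utilities.universe))
        if abs(u[0]) > 1e-12:
            raise ValueError("reference outcome (id 1) must have utility 0")
        if np.any(np.abs(u) > 10 + 1e-12):
            raise ValueError("agent utilities must lie in [-10, 10]")


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the main-task trial design."""

    n_trials: int = 300
    matched_fraction: float = 0.5
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    max_option_size: int = 4
    matched_tolerance_fraction: float = 0.2  # a fifth of the utility range
    max_rejections: int = 2000

    def __post_init__(self):
        if not 0.0 <= self.matched_fraction <= 1.0:
            raise ValueError("matched_fraction must lie in [0, 1]")
        if self.max_option_size > self.universe_size:
            raise ValueError("options cannot exceed the outcome universe")


def random_agent(
    rng: np.random.Generator,
    valuation_model: Optional[ModelSpec] = None,
    alpha_range: Tuple[float, float] = (2.0, 8.0),
    utility_range: Tuple[float, float] = (-10.0, 10.0),
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    rating_noise_sd: float = 0.5,
) -> AgentSpec:
    """Draw an agent uniformly from the estimation box (outcome 1 pinned at 0)."""
    u = rng.uniform(*utility_range, size=universe_size)
    u[0] = 0.0
    alpha = float(rng.uniform(*alpha_range))
    return AgentSpec(
        utilities=UtilityProfile.from_vector(u),
        precision_prior=PrecisionPrior(alpha=alpha, beta=1.0),
        model=valuation_model or ModelSpec(),
        rating_noise_sd=rating_noise_sd,
    )


def _random_option(rng: np.random.Generator, universe_size: int, max_size: int) -> Option:
    k = int(rng.integers(1, max_size + 1))
    ids = rng.choice(np.arange(1, universe_size + 1), size=k, replace=False)
    return Option(ids.tolist())


def _is_matched(
    left: Option,
    right: Option,
    profile: UtilityProfile,
    tolerance: float,
) -> bool:
    """Matched = similar expected utility but different entropy."""
    if left.cardinality == right.cardinality:
        return False
    d_eu = abs(expected_utility(left, profile) - expected_utility(right, profile))
    return d_eu <= tolerance


def is_matched_trial(
    trial: TrialOffer,
    profile: UtilityProfile,
    tolerance_fraction: float = 0.2,
) -> bool:
    """True if the trial has similar expected utility but different entropy.

    "Similar" means the EU difference does not exceed ``tolerance_fraction``
    of the range between the least and most preferred outcome.
    """
    u = profile.vector(len(profile.universe))
    tolerance = tolerance_fraction * float(u.max() - u.min())
    return _is_matched(trial.left, trial.right, profile, tolerance)


def generate_design(
    design: DesignSpec, profile: UtilityProfile, seed: int
) -> List[TrialOffer]:
    """Generate a main-task trial list by rejection sampling.

    Matched trials satisfy |EU(left) - EU(right)| <= tolerance with
    different option cardinalities (hence different entropy); the remaining
    trials are guaranteed NOT to satisfy that conjunction, so the matched
    count is exact.  The tolerance is ``matched_tolerance_fraction`` times
    the utility range (most minus least preferred outcome).

    If the constraints prove infeasible (e.g. an all-equal utility profile
    makes every unequal-cardinality pair matched), a warning is issued and
    the constraint relaxes to cardinality only.
    """
    rng = np.random.default_rng(seed)
    u = profile.vector(design.universe_size)
    tolerance = design.matched_tolerance_fraction * float(u.max() - u.min())
    n_matched = int(round(design.matched_fraction * design.n_trials))

    trials: List[TrialOffer] = []
    for t in range(design.n_trials):
        want_matched = t < n_matched
        offer = None
        for _ in range(design.max_rejections):
            left = _random_option(rng, design.universe_size, design.max_option_size)
            right = _random_option(rng, design.universe_size, design.max_option_size)
            matched = _is_matched(left, right, profile, tolerance)
            if matched == want_matched:
                offer = TrialOffer(trial_id=t + 1, left=left, right=right)
                break
        if offer is None:
            warnings.warn(
                "trial-design constraints infeasible; relaxing to a "
                "cardinality-only criterion",
                RuntimeWarning,
            )
            for _ in range(design.max_rejections):
                left = _random_option(rng, design.universe_size, design.max_option_size)
                right = _random_option(rng, design.universe_size, design.max_option_size)
                differs = left.cardinality != right.cardinality
                if differs == want_matched:
                    offer = TrialOffer(trial_id=t + 1, left=left, right=right)
                    break
            if offer is None:  # pragma: no cover - only for pathological specs
                raise RuntimeError("could not generate a feasible trial")
        trials.append(offer)

    # interleave matched / unmatched deterministically
    order = rng.permutation(design.n_trials)
    return [
        TrialOffer(trial_id=i + 1, left=trials[j].left, right=trials[j].right)
        for i, j in enumerate(order)
    ]


def simulate_choices(
    trials: Sequence[TrialOffer],
    agent: AgentSpec,
    seed: int,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> pd.DataFrame:
    """Simulate one choice per trial from the agent's softmax probabilities.

    Returns a frame with columns ``trial_id``, ``choice`` (+1 left / -1
    right) and ``outcome`` (realized outcome, sampled uniformly from the
    chosen option; recorded but unused by fitting).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for trial in trials:
        p_left, _ = choice_probabilities(
            trial, agent.utilities, agent.precision_prior, agent.model, universe_size
        )
        chose_left = rng.random() < p_left
        chosen = trial.left if chose_left else trial.right
        outcome = int(rng.choice(chosen.outcome_ids))
        rows.append(
            {
                "trial_id": trial.trial_id,
                "choice": 1 if chose_left else -1,
                "outcome": outcome,
            }
        )
    return pd.DataFrame(rows)


def generate_color_design(
    seed: int,
    n_trials: int = 180,
    n_training: int = 50,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
    max_option_size: int = 4,
) -> pd.DataFrame:
    """Generate the color control-task design (no utilities involved).

    Options contain 1-4 distinct colors; the first ``n_training`` trials are
    flagged as training (the association between colors and outcomes has to
    be learned first).  Returns the trial frame with a boolean ``training``
    column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trials):
        left = _random_option(rng, universe_size, max_option_size)
        right = _random_option(rng, universe_size, max_option_size)
        rows.append(
            {
                "trial_id": t + 1,
                "left_outcomes": ";".join(map(str, left.outcome_ids)),
                "right_outcomes": ";".join(map(str, right.outcome_ids)),
                "training": t < n_training,
            }
        )
    return pd.DataFrame(rows)


def emit_ratings(
    agent: AgentSpec,
    seed: int,
    n_repeats: int = 3,
    scale: float = 1.0,
    offset: float = 0.0,
) -> pd.DataFrame:
    """Emit noisy explicit ratings of each outcome.

    Each outcome is rated ``n_repeats`` times; a rating is an affine image
    of the true utility (``scale * u + offset``) plus Gaussian noise with sd
    ``agent.rating_noise_sd``.  Returns columns outcome_id, repeat, rating.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for outcome_id in agent.utilities.universe:
        true_u = agent.utilities[outcome_id]
        for rep in range(1, n_repeats + 1):
            noise = rng.normal(0.0, agent.rating_noise_sd) if agent.rating_noise_sd else 0.0
            rows.append(
                {
                    "outcome_id": outcome_id,
                    "repeat": rep,
                    "rating": scale * true_u + offset + noise,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def trials_to_frame(trials: Sequence[TrialOffer]) -> pd.DataFrame:
    """Serialize trials with semicolon-joined outcome id lists."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "left_outcomes": [";".join(map(str, t.left.outcome_ids)) for t in trials],
            "right_outcomes": [";".join(map(str, t.right.outcome_ids)) for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> List[TrialOffer]:
    return [
        TrialOffer(
            trial_id=int(row.trial_id),
            left=Option([int(i) for i in str(row.left_outcomes).split(";")]),
            right=Option([int(i) for i in str(row.right_outcomes).split(";")]),
        )
        for row in frame.itertuples()
    ]


def write_trials(trials: Sequence[TrialOffer], path: Path | str) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path: Path | str) -> List[TrialOffer]:
    return frame_to_trials(pd.read_csv(path))
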