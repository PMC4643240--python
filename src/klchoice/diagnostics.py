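"""Divergent-trial analysis.

On trials where the two options have similar expected utility but
different entropy, the KL-control and expected-utility models make
categorically different predictions.  A trial is *divergent* for a subject
when, under that subject's own fitted parameters, the KL model assigns one
side a choice probability of at least 70% while the EU model assigns that
same side at most 55%.  A subject's KL-consistency is the fraction of
their divergent trials on which the observed choice lands on the
KL-favored side; the group statistic is a one-sample t-test of the
per-subject proportions against chance (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_UNIVERSE_SIZE, PrecisionPrior, TrialOffer, choice_probabilities
from .fitting import SubjectFit

__all__ = [
    "DivergenceCriterion",
    "select_divergent_trials",
    "kl_consistency",
    "group_consistency_test",
]


@dataclass(frozen=True)
class DivergenceCriterion:
    """Probability thresholds defining a divergent trial."""

    kl_threshold: float = 0.70
    eu_threshold: float = 0.55

    def __post_init__(self):
        if not (0.5 <= self.eu_threshold < self.kl_threshold <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0.5 <= eu_threshold < kl_threshold <= 1"
            )


def select_divergent_trials(
    trials: Sequence[TrialOffer],
    kl_fit: SubjectFit,
    eu_fit: SubjectFit,
    criterion: DivergenceCriterion = DivergenceCriterion(),
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> pd.DataFrame:
    """Trials where the KL fit clearly prefers a side but the EU fit does not.

    Returns a frame with trial_id, the KL-favored side (+1 left / -1
    right) and both models' probabilities for that side.  An empty frame
    is a valid result (such subjects are excluded from the group
    statistic).
    """
    rows = []
    for trial in trials:
        p_kl_left, p_kl_right = choice_probabilities(
            trial,
            kl_fit.utilities_hat,
            PrecisionPrior(kl_fit.alpha_hat),
            kl_fit.spec,
            universe_size,
        )
        p_eu_left, p_eu_right = choice_probabilities(
            trial,
            eu_fit.utilities_hat,
            PrecisionPrior(eu_fit.alpha_hat),
            eu_fit.spec,
            universe_size,
        )
        qualifying = []
        for side, p_kl, p_eu in (
            (1, p_kl_left, p_eu_left),
            (-1, p_kl_right, p_eu_right),
        ):
            if p_kl >= criterion.kl_threshold and p_eu <= criterion.eu_threshold:
                qualifying.append((side, p_kl, p_eu))
        if len(qualifying) > 1:  # impossible while kl_threshold > 0.5; guarded
            raise RuntimeError(
                f"trial {trial.trial_id}: both sides satisfy the divergence criterion"
            )
        if qualifying:
            side, p_kl, p_eu = qualifying[0]
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "kl_side": side,
                    "p_kl": p_kl,
                    "p_eu": p_eu,
                }
            )
    return pd.DataFrame(rows, columns=["trial_id", "kl_side", "p_kl", "p_eu"])


def kl_consistency(choices: pd.DataFrame, divergent: pd.DataFrame) -> float:
    """Fraction of divergent trials choosing the KL-favored side.

    Raises on an empty divergent set: such a subject carries no
    information and is excluded from the group test.
    """
    if divergent.empty:
        raise ValueError("no divergent trials for this subject (excluded)")
    merged = divergent.merge(choices[["trial_id", "choice"]], on="trial_id")
    if len(merged) != len(divergent):
        raise ValueError("choices missing for some divergent trials")
    return float((merged["choice"] == merged["kl_side"]).mean())


def group_consistency_test(
    proportions: Sequence[float], alternative: str = "greater"
) -> Tuple[float, float]:
    """One-sample t-test of per-subject KL-consistency proportions vs 0.5."""
    x = np.asarray(proportions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two subjects")
    res = stats.ttest_1samp(x, 0.5, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
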