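"""Trial-by-trial choice regressions.

Per subject, choices are regressed on the between-option differences in
expected utility, risk and entropy gain; a second-level one-sample t-test
on the per-subject coefficients gives the group result.  Model evidence
with and without the entropy predictor is compared through BIC scores in
log-evidence orientation (higher is better).

Sign conventions: the main task uses (left - right) predictor differences
with the response "chose left", so a positive coefficient always means the
subject *seeks* that quantity.  The color control task regresses "chose
right" on the (right - left) entropy difference plus one presence confound
per color (+1 present right only / -1 present left only / 0 otherwise) —
the same alignment, so positive again means seeking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .core import TrialOffer, UtilityProfile, entropy_gain, expected_utility, risk
from .comparison import bic_score

__all__ = [
    "RegressionResult",
    "build_design",
    "fit_choice_regression",
    "group_level_test",
    "count_effect_signs",
    "fit_color_regression",
    "DegenerateTestError",
    "RankDeficiencyError",
]


class DegenerateTestError(ValueError):
    """Second-level test undefined (zero variance and zero mean)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass
class RegressionResult:
    """One subject's regression fit.

    ``bic_score`` uses the log-evidence convention (LL minus half the
    parameter count times log n), so it worsens (decreases) as parameters
    are added at equal likelihood.
    """

    subject_id: Optional[int]
    coefficients: Dict[str, float]
    pvalues: Dict[str, float]
    significant: Dict[str, bool]
    log_likelihood: float
    n_params: int
    bic_score: float
    n_trials_used: int
    separation_flag: bool = False
    family: str = "logistic"


def build_design(
    trials: Sequence[TrialOffer],
    profile: UtilityProfile,
    include_entropy: bool = True,
    choices: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, Optional[np.ndarray]]:
    """Design matrix of (left - right) predictor differences, plus response.

    Predictors are the trial-wise differences in expected utility, risk
    and (optionally) entropy gain, with an intercept column.  The response
    (returned when ``choices`` is given) is the +1 left / -1 right choice
    aligned on trial_id.
    """
    rows = []
    for t in trials:
        row = {
            "trial_id": t.trial_id,
            "d_expected_utility": expected_utility(t.left, profile)
            - expected_utility(t.right, profile),
            "d_risk": risk(t.left, profile) - risk(t.right, profile),
        }
        if include_entropy:
            row["d_entropy"] = entropy_gain(t.left) - entropy_gain(t.right)
        rows.append(row)
    design = pd.DataFrame(rows).set_index("trial_id")
    design.insert(0, "intercept", 1.0)

    response = None
    if choices is not None:
        aligned = choices.set_index("trial_id").loc[design.index, "choice"]
        response = aligned.to_numpy(dtype=float)
    return design, response


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns whose removal restores full column rank
        collinear = [
            col
            for i, col in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"design matrix rank deficient; collinear columns: {collinear}"
        )


def fit_choice_regression(
    design: pd.DataFrame,
    response: np.ndarray,
    family: str = "logistic",
    subject_id: Optional[int] = None,
    coef_cap: float = 50.0,
    alpha_level: float = 0.05,
) -> RegressionResult:
    """Fit a choice regression and score it with a log-evidence BIC.

    ``family='logistic'`` fits a Bernoulli GLM on the 0/1-recoded choice
    (the default: it yields a well-defined likelihood of the observed
    responses).  ``family='linear'`` fits ordinary least squares on the
    +/-1 response with a Gaussian likelihood.  Perfect separation in the
    logistic family is flagged and coefficients are capped at ``coef_cap``.
    """
    y = np.asarray(response, dtype=float)
    n, k = design.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for {k} parameters")
    _check_rank(design)

    separation = False
    if family == "logistic":
        y01 = (y + 1.0) / 2.0
        try:
            with np.errstate(all="ignore"):
                fit = sm.GLM(y01, design, family=sm.families.Binomial()).fit(
                    maxiter=200
                )
            params = fit.params
            pvals = fit.pvalues
        except Exception:
            # perfect-separation style failure: fall back to a ridge-
            # regularized fit and flag it
            separation = True
            with np.errstate(all="ignore"):
                fit = sm.Logit(y01, design).fit_regularized(
                    alpha=1e-4, disp=False, maxiter=500
                )
            params = fit.params
            pvals = pd.Series(np.nan, index=design.columns)
        if np.any(np.abs(params) > coef_cap):
            separation = True
            params = params.clip(-coef_cap, coef_cap)
        eta = design.to_numpy() @ np.asarray(params)
        p = expit(eta)
        eps = 1e-12
        ll = float(np.sum(y01 * np.log(p + eps) + (1 - y01) * np.log(1 - p + eps)))
    elif family == "linear":
        fit = sm.OLS(y, design).fit()
        params = fit.params
        pvals = fit.pvalues
        ll = float(fit.llf)
    else:
        raise ValueError(f"unknown family {family!r}")

    coeffs = {c: float(params[c]) for c in design.columns}
    pd_pvals = {c: float(pvals[c]) for c in design.columns}
    return RegressionResult(
        subject_id=subject_id,
        coefficients=coeffs,
        pvalues=pd_pvals,
        significant={c: bool(p < alpha_level) for c, p in pd_pvals.items()},
        log_likelihood=ll,
        n_params=k,
        bic_score=bic_score(ll, k, n),
        n_trials_used=n,
        separation_flag=separation,
        family=family,
    )


def group_level_test(
    coefficients: Sequence[float] | pd.Series,
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """One-sample t-test of per-subject coefficients against zero.

    ``alternative`` may be 'two-sided' or 'greater' (the one-tailed test
    used for the control study).  If the coefficients have zero variance
    the t statistic is infinite (degenerate) for a nonzero mean and the
    test is undefined for a zero mean.
    """
    x = np.asarray(coefficients, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two subjects for a group-level test")
    sd = np.std(x, ddof=1)
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        if np.all(x == 0):
            raise DegenerateTestError("all coefficients are exactly zero")
        return math.copysign(math.inf, float(np.mean(x))), 0.0
    res = stats.ttest_1samp(x, 0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def count_effect_signs(
    table: pd.DataFrame, predictors: Optional[Sequence[str]] = None
) -> Dict[str, int]:
    """Number of subjects with a strictly positive coefficient per predictor."""
    cols = list(predictors) if predictors is not None else list(table.columns)
    return {c: int((table[c] > 0).sum()) for c in cols}


def fit_color_regression(
    trials: pd.DataFrame,
    choices: pd.DataFrame,
    n_colors: int = 6,
    include_interaction: bool = False,
    subject_id: Optional[int] = None,
    family: str = "logistic",
) -> RegressionResult:
    """Control-task regression: entropy seeking with color confounds.

    The response is the choice of the right option; the explanatory
    variable is the (right - left) entropy difference, so a positive
    coefficient means entropy seeking.  One confound per color codes its
    presence (+1 right only, -1 left only, 0 both or neither); optional
    entropy-by-color interactions let a color's implicit value vary with
    option size.  Training trials and trials where either option holds
    four items (ceiling) are excluded.
    """
    merged = trials.merge(choices, on="trial_id")
    if "training" in merged.columns:
        merged = merged[~merged["training"].astype(bool)]

    rows = []
    for row in merged.itertuples():
        left = {int(i) for i in str(row.left_outcomes).split(";")}
        right = {int(i) for i in str(row.right_outcomes).split(";")}
        if len(left) >= 4 or len(right) >= 4:
            continue  # ceiling filter
        rec = {
            "trial_id": row.trial_id,
            "d_entropy": math.log(len(right)) - math.log(len(left)),
            "chose_right": 1.0 if row.choice == -1 else 0.0,
        }
        for color in range(1, n_colors + 1):
            presence = (1 if color in right else 0) - (1 if color in left else 0)
            rec[f"color_{color}"] = float(presence)
            if include_interaction:
                rec[f"entropy_x_color_{color}"] = rec["d_entropy"] * presence
        rows.append(rec)
    if not rows:
        raise ValueError("ceiling/training filters removed every trial")

    frame = pd.DataFrame(rows).set_index("trial_id")
    response01 = frame.pop("chose_right").to_numpy()
    design = frame.copy()
    design.insert(0, "intercept", 1.0)
    # drop confound columns with no variation (color never differentially present)
    keep = [c for c in design.columns if c == "intercept" or design[c].std() > 0]
    design = design[keep]
    return fit_choice_regression(
        design, 2.0 * response01 - 1.0, family=family, subject_id=subject_id
    )
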