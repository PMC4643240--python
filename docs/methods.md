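# Methods

## Choice models

An option is a uniform lottery over `k` distinct outcomes (`1 ≤ k ≤ 4`)
from a universe of `K = 6`. Given utilities `u(o)`, the preferred outcome
distribution is the softmax `C(o) = exp(u(o)) / Σ exp(u(o'))`, normalized
over the full 6-outcome universe (not the per-trial union of offered
outcomes). This mapping makes `ln C(o) = u(o) − ln Z` with `Z` a constant
shared by both options of a trial, so the KL-control value

    V_KL(option) = −D_KL[Q ‖ C] = ln k + (1/k) Σ_{o∈option} u(o) − ln Z

is, up to the common constant, an entropy bonus plus expected utility.
The expected-utility variant drops the `ln k` term; its option rankings
coincide with classical expected utility. Natural logarithms are used
throughout (values in nats), and `0 · ln 0 = 0` for outcomes outside an
option's support.

Choice probabilities are a two-option softmax of the values scaled by a
precision `γ`. Precision is the mean of a gamma prior with shape `α` and
rate `β = 1`; in a one-shot task there is no evidence on which to update
precision within a trial, so `γ = α` acts exactly as an inverse
temperature. No policy prior beyond the option values enters the softmax.

Consequences exploited by the tests: choice probabilities are invariant
to adding a constant to all utilities; the KL and EU models coincide
exactly whenever the two options have equal cardinality (the entropy
terms cancel); and for expected-utility-matched options the KL model's
preference is strictly increasing in cardinality.

## Synthetic study designs

The generator emulates the behavioral design the analysis was built for:
300 main-task trials per subject, with half constructed to have similar
expected utility but different entropy. "Similar" means the EU difference
does not exceed one fifth of the range between the least and most
preferred outcome. Construction is by rejection sampling over random
option pairs (cardinalities uniform over 1–4, outcomes drawn without
replacement); *unmatched* trials are additionally resampled until they
violate the matched conjunction, so exactly half the trials satisfy it.
If a profile makes the constraint infeasible (e.g. a zero tolerance), the
generator warns and relaxes to a cardinality-only criterion. The
distribution of option cardinalities across trials is a design choice
here (uniform over feasible sizes); nothing in the emulated study pins it
down.

The color control task mirrors the main task without utilities: 180
trials of 1–4 colors per option, the first 50 flagged as training and
excluded from analysis, outcomes sampled uniformly from the chosen
option.

Simulated agents draw utilities uniformly in the estimation box
(outcome 1 pinned at 0, others in `[-10, 10]`) and precision uniformly in
`[2, 8]`, choose through the model softmax, and emit explicit ratings as
an affine image of their true utilities plus Gaussian noise
(sd 0.5 by default, three repeats per outcome). Everything is a pure
function of (spec, seed).

What the generator does *not* emulate: hunger or satiety dynamics,
preference drift over the session, snack identities, the 18→6 item
down-selection, and lapses or motor errors. Passing recovery tests
therefore show that the estimation machinery is consistent under the
model's own assumptions, not that real subjects satisfy them.

## Regression analysis

Per subject, choices are regressed on the trial-wise (left − right)
differences in expected utility, risk (population variance of an
option's utilities) and entropy gain, with an intercept (included by
choice; its presence is configurable in spirit by editing the design
matrix). The response is the choice of the left option, so a positive
coefficient always means seeking the quantity. The default likelihood
family is Bernoulli logistic on the 0/1-recoded choice — it yields a
well-defined log-likelihood of the observed responses for the BIC — with
an ordinary-least-squares linear-probability family available for a
literal general-linear-model reading. Perfect separation is flagged and
coefficients are capped (default 50); rank-deficient designs raise an
error naming the collinear columns.

The color-task regression uses the choice of the *right* option as the
response and the (right − left) entropy difference as the predictor —
the two sign conventions are deliberately aligned so that a positive
coefficient again means entropy seeking — plus one confound per color
(+1 present only in the right option, −1 only in the left, 0 otherwise)
and optional entropy-by-color interactions. Trials where either option
holds four items are excluded to avoid ceiling effects.

Group-level inference is a one-sample t-test on the per-subject
coefficients (two-sided by default; one-tailed available, as appropriate
for the directional entropy prediction in the control task).

## Maximum-likelihood fitting

Free parameters per subject: five utilities (outcome 1 pinned at 0 to
remove the softmax shift degeneracy) and, in the estimated-precision
variants, `α`. Boxes: `u ∈ [-10, 10]`, `α ∈ [2, 8]`; the fixed variant
uses `α = 4`. Optimization is L-BFGS-B with analytic gradients on a
vectorized form of the likelihood (the log-preference normalizer cancels
between options, leaving an affine function of the utilities), from 10
uniform random interior starts by default, `ftol 1e−6`; the best optimum
is returned and estimates on the box boundary are reported as-is.
Evidence is a BIC score in log-evidence orientation,
`LL − (k/2) ln n_trials`, with `k = 5` or `6` depending on whether `α` is
free. Utility–precision trade-offs are only weakly identified when
fitted utilities are large (choices saturate), which shows up as
occasional `α` estimates at the bounds — the published parameter tables
show the same pinning.

## Random-effects model selection

Subject-level BIC scores are treated as log model evidences. The group
analysis places a Dirichlet distribution over population model
frequencies (uniform prior, `α₀ = 1`) and iterates the variational
fixed point — responsibilities `u_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))`
normalized per subject, then `α_k = α₀ + Σ_n u_nk` — until the change in
`α` falls below 1e−6 (error after 10⁴ iterations). Exceedance
probabilities (the posterior probability that a model is the most
frequent) are computed exactly for two models via the Beta survival
function at 1/2, and by seeded Dirichlet Monte Carlo (10⁶ draws by
default) for three or more. Protected exceedance probabilities postdate
this scheme and are out of scope.

The log-evidence orientation matters: the packaged per-subject scores
are negative with the winning model *less* negative, which is consistent
only with `LL − (k/2) ln n`, not with the classical `−2LL + k ln n`.
The packaged tables' printed totals were evidently computed before the
entries were rounded to two decimals; recomputed column sums agree with
them to within 0.03, and tests allow 0.05 for the accumulated rounding
of 20 entries.

## Divergent trials

Using each subject's own fitted parameters under the two
estimated-precision models, a trial is divergent when the KL model puts
at least 0.70 on one side while the EU model puts at most 0.55 on that
same side (the literal threshold pair; no additional requirement that
the EU model prefer the other side). Since the KL threshold exceeds 0.5,
at most one side can qualify; a guard raises if both somehow do. A
subject's KL-consistency is the fraction of divergent trials whose
observed choice lands on the KL-favored side; subjects with no divergent
trials are excluded, and the group test is a one-tailed one-sample
t-test of the proportions against 0.5.

## Numerical and degenerate-case choices

- Softmax and likelihood evaluations use `log1p`/`logaddexp`/`expit`
  forms, so extreme precisions or utilities do not overflow.
- A group-level t-test on coefficients with (numerically) zero variance
  returns an infinite t for a nonzero mean and raises for an all-zero
  vector.
- Zero-variance vectors in the rating correlation yield NaN with a
  warning rather than an arbitrary value.
- Sub-seeds for pipeline stages derive deterministically from the master
  seed and the stage name, so stages can be rerun independently while
  the whole run stays reproducible from one integer.

## Problem sizes

The validation studies run at the emulated study's natural scale —
cohorts of 20 subjects at 300 trials each — with 10 replicate studies
for the sign-recovery checks and 20 simulated subjects for parameter
recovery; these sizes give the group tests high power while keeping the
full suite quick on a single core.

## Known limitations

- The real behavioral data are not deposited, so subject-level results
  (e.g. the observed 75% KL-consistency) cannot be recomputed; only the
  published table aggregates and simulation-based properties are
  checked.
- The fitted-precision parameter is identified through the entropy
  weighting and saturates at its bounds for near-deterministic subjects.
- The regression's likelihood family for the published BIC tables cannot
  be pinned down from their description; the packaged scores are used
  as given rather than refit.
- Hierarchical (group-prior) estimation and within-trial precision
  updating are deliberately out of scope.
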