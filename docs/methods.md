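# Methods

## The skill index

An attempt's mistake score accumulates 1 point per minor mistake and 5 per
major mistake; an attempt whose total reaches 5 is a *major-mistake attempt*
(`MistakeRubric`, fully configurable). The major-mistake average after
attempt *n* is the cumulative proportion

    MMA(n) = (# major-mistake attempts among 1..n) / n.

The accumulation runs from the very first attempt, not per period: the
worked values the method is checked against (1/6 at attempt 6, 5/19 at the
peak, 6/36 and 10/85 at later period endpoints) are all consistent only with
the cumulative-from-start definition. `mma_series` computes it as an integer
cumulative sum divided by n, so values are exact to double precision, and a
brute-force recount oracle backs it in the tests.

Minor mistakes are deliberately excluded from the index: they are strongly
confounded with specimen variability and strategy changes, whereas a major
mistake (an unrepairable, attempt-ending error) is a clean read-out of
technical performance.

## Periods and drop statistics

Segmentation is user-supplied: breakpoints list the last attempt of each
period except the final one (default `5,12,19,36,85`, six periods over 132
attempts). No automatic change-point detection is offered — the period
structure of a learning curve is an interpretive choice, and pretending to
automate it would overstate the method.

For period *k*, `mma_start` is the cumulative MMA at the previous period's
last attempt (0 before any attempt), `mma_end` the cumulative MMA at its own
last attempt, `absolute_drop = mma_start − mma_end`, and
`drop_rate = absolute_drop / NOA`. Drops therefore telescope across any
partition — the tests assert this for random partitions.

Two time statistics coexist on purpose:

* `tct_series` (trend fitting) *excludes* zero-time attempts. An attempt
  aborted by a major mistake is never timed; its recorded 0 is a missing
  observation, and including it would corrupt a completion-time trend.
* `PeriodSummary.tct_average` *includes* them (mean of `total_time` over all
  attempts of the period). This mirrors the convention of published period
  tables for this protocol, whose printed averages are reproducible only
  with the zero rows in the denominator. The field should be read as "mean
  recorded time per attempt", not "mean completion time".

## Trend fits

`fit_trend` offers ordinary least squares (`linear`) and a log-linear
exponential fit (`exponential`): OLS of log y on x, with R² evaluated on the
*original* scale from back-transformed fitted values, so linear and
exponential fits are comparable on the same response. Constant y yields a
well-defined line with R² = NaN (the conventional 1 − SS_res/SS_tot is 0/0).
A time-series (ARIMA-style) model of the curve is out of scope: only the
trend fits and their R² are part of the method's claims.

## The Poisson gate

Per-attempt indicators are Bernoulli, hence structurally *under*dispersed
against Poisson (variance = p(1−p) ≤ p), so the gate first accumulates
counts over non-overlapping blocks of consecutive attempts
(`GateConfig.block_size`, default 4 ≈ one training session of the protocol
emulated here). A trailing short block is dropped rather than pooled so
block counts stay identically distributed under the null. Blocked counts are
approximately Poisson when the per-attempt rate is small — at plateau rates
around 0.04 the binomial dispersion deficit (factor 1−p) is negligible.

Two tests are provided:

* **Index of dispersion** (default): D = (n−1)s²/x̄ over n blocks, compared
  to the upper (1−α) quantile of χ²(n−1). Upper-tail by design:
  overdispersion is the signature of systematic error; a two-sided variant
  is not needed to declare a plateau.
* **Goodness of fit**: observed count-class frequencies (0, 1, …, tail
  merged upward until the expected tail mass is ≥ 1, never below two
  classes) against Poisson(λ̂), df = #classes − 2 floored at 1. With only
  two classes it degenerates to a presence/absence check and says so in a
  warning.

Verdicts use the field's vocabulary: *positive* = Poisson not rejected =
mistakes compatible with randomness; *negative* = systematic structure
remains. `detect_plateau` runs the configured test on each period in
chronological order, reports periods too short to block as *untestable*
(never silently skipped), and returns the first positive period as the
efficient skill threshold. Because the statistic is fixed and only the
threshold moves, the set of positive periods grows monotonically as α
shrinks; the tests assert this.

`lambda_hat` in a `DispersionResult` is the mean count per block;
`estimate_lambda` reports the per-attempt rate (majors/attempts), the only
unit under which rate × period length is an integer event count. Published
per-period λ values for this method are not internally consistent with any
single unit (per attempt, per block, or per session); defining λ per attempt
and exposing block λ̂ separately makes the computation auditable.

Small-sample behaviour, honestly stated: with few blocks and small λ the
discrete null distribution of D lies strictly inside the χ² tail and the
test is **conservative** — simulated type-I error is ≈ 0.014 at (λ=0.5,
n=5 blocks) and ≈ 0.025 at (λ=1, n=5) versus nominal 0.05, converging to
nominal for λ·n ≳ 10. A conservative gate errs toward *not* certifying a
plateau, which is the safe direction for a training endpoint, but users
should prefer longer periods or larger blocks over testing 5-block periods.
Exact conditional or bootstrap corrections are intentionally out of scope.

α defaults to 0.05, the level implied by the χ² threshold 3.841
conventionally used with this method. No multiple-testing correction is
applied across periods — the gate is a sequential stopping rule, not a
family of simultaneous claims.

## Synthetic trainee generator

`SimConfig` describes a three-phase per-attempt major-mistake hazard:

| parameter | default | meaning |
|---|---|---|
| `n_attempts` | 132 | trial length |
| `phase_bounds` | (19, 85) | last attempt of the unstable / learning phases |
| `p_unstable` | 0.25 | constant hazard in the unstable phase |
| `p0`, `p_plateau` | 0.10, 0.04 | learning-phase hazard endpoints |
| `decay` | 0.05 /attempt | exponential decay rate toward `p_plateau` |
| `tct_start`, `tct_floor` | 2500 s, 1200 s | task-time curve endpoints |
| `tct_decay` | 0.02 /attempt | task-time decline rate |
| `tct_cv` | 0.25 | lognormal noise CV on task time |

Defaults depict the single-operator trial structure the method was developed
on: a 132-attempt trial whose first ~19 attempts are erratic (observed early
major rate ≈ 5/19), whose plateau major rate is ≈ 2/47–4/49, and whose
period mean times fall from ≈ 2,500 s to ≈ 1,240 s. The unstable phase is
modeled as a constant high hazard because no quantitative structure for
early-phase behaviour is established; it is an explicit invention. Minor
mistakes are generated independently of majors (scores 0/1/2 with
probabilities 0.50/0.35/0.15), majors land on the three task stages with
probabilities (2/11, 8/11, 1/11) — adventitial dissection dominates — and
aborted attempts record time 0 with absent stage times, exactly as real logs
do. Stage times split the total by fixed proportions with the third stage
(suturing) largest; the last stage absorbs rounding so stage times always
sum to the total.

One seed feeds three independent sub-streams (majors, scores/stages, times),
so changing the time-noise settings cannot perturb the mistake sequence;
output CSV is byte-identical for identical config.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: inter-session gaps affecting error
probability (warm-up/decay effects), dependence between speed and error
risk, specimen-difficulty heterogeneity, and any autocorrelation in mistake
occurrence beyond the hazard trend.

## Parameter recovery

`recover_parameters` fits p(t) = p_plateau + Δ·exp(−k·(t−1)), Δ ≥ 0, by
maximizing the exact Bernoulli log-likelihood (L-BFGS-B, eight deterministic
starts, box bounds p ∈ [1e−6, 1−1e−6], k ∈ [0, 10]). The Δ ≥ 0
parametrization builds the "decaying toward plateau" shape into the model;
when Δ̂ → 0 the decay rate is unidentified and is reported as 0. Datasets
with no majors at all sit on the p → 0 boundary and are returned with
`boundary=True` rather than an error.

Identifiability caveat: at realistic effect sizes (p0 = 0.3 decaying at
k = 0.05 to a 0.05 plateau over 2,000 attempts) the plateau rate is sharply
identified (95% recovery interval ≈ [0.039, 0.060]) while p0 and k are
individually weak — only ~60 early attempts inform them jointly, and their
95% recovery intervals are wide and partly bound-limited. The acceptance
test states coverage against simulation-based intervals frozen from a
400-replicate recovery study at that truth.

## Numerical and presentation choices

* Internal arithmetic is full double precision; rounding happens only at
  presentation (`round_half_up`, ties away from zero): MMA and drops to 3
  decimals, drop rates to 3–4, χ² thresholds to 3.
* Problem sizes in the test suite: MMA oracle over 200 random sequences up
  to length 1,000; gate calibration at 2,000 replicates per (λ, n) point;
  power and consistency of the operating characteristics at 150–600
  replicates on a 2,000-attempt plateau; recovery coverage over 20 fresh
  2,000-attempt fits. These sizes give Monte-Carlo standard errors small
  enough for 3σ assertions while keeping the suite fast.
* Degenerate inputs are defined, not crashed on: all-zero counts →
  trivially positive with a `degenerate` flag; constant y → NaN R²;
  periods too short to block → `untestable`.

## Known limitations

* Breakpoints are an input; two analysts can draw different period tables
  from the same curve.
* The gate's verdict depends on `block_size`; session-aligned blocking
  would be preferable when session boundaries are recorded.
* The dispersion test is conservative for short periods (see above).
* Single-operator logs only: no hierarchical pooling across trainees.
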