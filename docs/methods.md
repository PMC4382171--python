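# Methods

## The model

`affectcpt` models binary choices between two-branch loss prospects — lose
`x` with probability `p`, nothing otherwise — with cumulative prospect
theory (CPT) restricted to the loss domain.

Value function (outcome sensitivity `0 < α ≤ 1`):

    v(x) = −(−x)^α,   x ≤ 0

convex for losses, `v(0) = 0`. Probability weighting (curvature `0 < γ ≤ 1`,
elevation `0 < δ ≤ 10`):

    w(p) = δ p^γ / (δ p^γ + (1 − p)^γ)

with `w(0) = 0` and `w(1) = 1` returned exactly. Lower `γ` flattens the
mid-range of the function (an inverse-S shape, i.e. attenuated probability
sensitivity); higher `δ` elevates it (more risk aversion for losses). With
outcomes ranked `0 ≥ x₁ ≥ … ≥ x_k`, the decision weight of `x_j` is the
telescoping difference

    π_j = w(p_j + … + p_k) − w(p_{j+1} + … + p_k)

and a prospect's valuation is `V = Σ_j v(x_j) π_j`. For the two-branch
design prospects this collapses to `V = v(x) · w(p)`.

Choice probabilities combine a softmax of the raw valuations with a uniform
guessing process (`0 < g ≤ 1`):

    p(A,B) = (1 − g) · e^{V(A)} / (e^{V(A)} + e^{V(B)}) + g/2

Two variants exist for model comparison: `sensitivity_only` replaces the
guessing mixture with a sensitivity parameter `φ` scaling the valuation
difference, and `both` uses `g` and `φ` together. `φ` bounds are not part
of the published parameterization; the package uses `0 < φ ≤ 10`.

The softmax operates on raw currency-scale valuations (no rescaling), so
fitted `g`/`φ` behavior depends on the currency unit of the magnitudes;
this mirrors the modelling convention the design comes from and is
deliberate. For numerical safety the exponent difference `φ(V(A) − V(B))`
is clipped at ±500 before exponentiation.

## Fitting

CPT is fitted per participant and per domain (affect-rich / affect-poor) by
maximum likelihood, using the deviance

    G² = −2 Σ_i ln f_i(y | θ)

where `f_i` is the predicted probability of the observed choice on trial
`i`. Predicted probabilities are floored at `1e-12` before the log: the
`sensitivity_only` rule can assign probability ~0 to an observed choice,
and the floor keeps the objective finite rather than discarding the trial.

The optimization is two-stage:

1. **Grid search** over α, γ ∈ {0.1, …, 1.0} (step 0.1),
   δ ∈ {0.1, 0.25, 0.5, 1, 2, 4, 7, 10}, g ∈ {0.02, 0.1, 0.3, 0.6, 0.9},
   and φ ∈ {0.05, 0.2, 1, 5} where applicable — log-ish spacing for the
   unbounded-feeling axes, covering the full parameter box. The grid is
   evaluated fully vectorized; ties are broken by enumeration order.
2. **Simplex refinement** (Nelder–Mead, objective tolerance `1e-8`,
   parameter tolerance `1e-6`, at most 2000 iterations per start) from the
   20 best grid points. The simplex runs in a transformed space: each
   parameter is mapped onto ℝ by a scaled logit over its interval, so every
   iterate respects the bounds smoothly. A single transform family is used
   for all parameters (including δ and φ) because a plain log transform
   would leave their upper bounds unenforced, and penalty walls distort the
   simplex geometry. Open lower bounds (`0 < α`, …) are implemented
   as `≥ 1e-6`.

Because `g = 1` (pure guessing) is the closed endpoint of its interval, the
logit transform can only approach it asymptotically; the analytic chance
fit (`g = 1`, `G² = −2N ln ½`, e.g. 116.45 at N = 84) is therefore always
evaluated as an extra candidate. This guarantees the nesting property: a
fitted `G²` never exceeds the chance deviance. The best candidate by `G²`
wins (first-found on ties), making the whole fit deterministic for a fixed
dataset and grid.

Model comparison across choice rules uses `BIC = G² + k ln N` with `k` the
number of free parameters (4 for `guess_only` and `sensitivity_only`, 5 for
`both`) and `N` the number of choices entering the fit.

Two implementation details matter for numerical agreement with direct
formula evaluation. First, the full-probability tail of a complete lottery
is pinned to exactly 1 when computing decision weights: `w` has unbounded
slope at `p = 1`, so float summation order would otherwise perturb the top
weight by ~1e-7. Second, likelihood terms are collapsed to unique
(problem, choice) patterns with multiplicities before the deviance sum — an
exact reformulation that makes repeated-design fits several times faster.

## Synthetic data

No choice data are distributed with the package; the generator reproduces
the study structure so every stage is testable end to end.

* **Side effects and WTP.** Four side effects are ranked per participant
  (random permutation) and assigned willingness-to-pay amounts drawn
  log-normally (default median 50 currency units, log-SD 0.8 — a
  right-skewed valuation distribution with most draws in the tens of
  units), sorted so WTP is monotone in severity.
* **Problem templates.** 42 two-branch problem templates pair a
  smaller-but-likelier loss against a larger-but-rarer one, built from the
  8 design probabilities {0.05, 0.08, 0.15, 0.18, 0.5, 0.53, 0.95, 0.98}
  (four levels, two probabilities per level 0.03 apart). Candidate pairings
  of severity ranks and probability pairs are scored by |log EV ratio|
  under pilot median WTPs (defaults 100/60/35/20 by severity rank, chosen
  so that ≥ 42 candidates satisfy the default EV-ratio tolerance of 1.5);
  selection first covers each of the 8 probabilities with its best
  candidate, then fills by global rank. An infeasible tolerance is relaxed
  with a warning. Each participant's problems substitute her own WTPs into
  the fixed templates, so individual EV comparability is approximate — as
  in the real paradigm, where only the pilot medians were EV-balanced.
* **Domains.** The affect-poor twin of each affect-rich problem is
  monetarily identical (side-effect labels replaced by the WTP amounts);
  all behavioral differences between domains are produced by the
  domain-specific generating parameters.
* **Trial sequence.** Each problem appears twice per domain, once with each
  option shown alone in the evaluation phase; the 84 slots per domain are
  shuffled by seed and interleaved in alternating domain blocks of three.
* **Choices.** Bernoulli draws from the choice rule under per-domain
  parameters drawn from truncated normals within the CPT bounds. The
  default generating means/SDs are the published group-level estimates:
  affect-poor γ 0.77 (0.24), δ 0.99 (1.63), α 0.73 (0.21), g 0.07 (0.11);
  affect-rich γ 0.43 (0.33), δ 2.47 (3.10), α 0.79 (0.26), g 0.12 (0.19).
* **Affective ratings.** 1–10 upset ratings are emitted for schema
  completeness (side effect stochastically ≥ matched loss); no inferential
  statistics are computed on them.

What the generator does **not** emulate: response-time structure, learning
or fatigue across the session, violations of CPT (the simulated agent *is*
the fitted model family), heterogeneity beyond independent truncated-normal
parameters, or WTP elicitation biases. Passing recovery tests therefore
show the estimation machinery is consistent under the design, not that the
model is correct for human data.

## Behavioral summaries

* **EV-maximization rate**: percentage of non-tied trials where the chosen
  option had the higher expected value; tied-EV trials are excluded and
  counted.
* **Preference reversals**: matched cross-domain pairs with differing
  choices. Pairs are matched on (template, evaluated option) by default
  (up to 84 comparisons per participant); template-level majority matching
  is available behind a flag since the published definition of
  "corresponding problems" does not fix the convention.
* Group tables report mean, sample SD (n − 1 denominator), and median;
  participants with undefined rates are excluded per rate with the count
  reported.

## Regressors

Per trial, the fitted domain-specific parameters yield a subjective value
`v(x)` and a decision weight (= `w(p)` for two-branch prospects) of the
option presented alone (evaluation phase, duration 4 s) or chosen (decision
phase, duration = response time). Events are exported as whitespace
three-column timing files (onset, duration, weight): an unmodulated
intercept plus value- and weight-modulated files. Modulated columns are
mean-centered per run by default — the timing-file equivalent of
orthogonalizing each modulator against its intercept — and the centering is
toggleable. Simulated onsets jitter fixations uniformly on 2–9 s
(evaluation→decision) and 3–11 s (decision→next trial). HRF convolution,
derivatives, and motion regressors are downstream GLM concerns and out of
scope.

## Validation studies and problem sizes

* **Parameter recovery**: 20 replicates × 20 participants × 2 domains,
  840 trials per domain (the 84-trial design repeated 10×). Reported:
  Spearman rank correlation between generating and recovered γ pooled
  across domains within a replicate, and the fraction of replicates where
  the mean recovered γ is lower in the affect-rich condition.
* **EV-maximization direction**: 20 seeded cohorts of 23 participants at
  the default generating means; the affect-rich rate is expected lower.
* **Guessing-reversal null**: ≥ 10,000 matched pairs simulated with
  `g = 1` in both domains; the reversal rate concentrates at 50%.

These sizes were chosen as the smallest that make the checks statistically
stable; all are recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

* Loss domain only: no gains, mixed prospects, or loss-aversion parameter.
* Point estimates only — no standard errors, hierarchical pooling, or
  Bayesian estimation.
* The published per-participant estimates come from human data that are not
  distributed; they enter only as generating distributions for simulation,
  so published sample statistics (e.g. specific reversal percentages) are
  not reproduction targets.
* The exact 42-problem list of the original design is treated as
  configurable input; the package reproduces its construction constraints,
  not the verbatim list.
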