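# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Game layer

The stage game uses the payoff ordering T > R > P > S with the default
matrix (7, 5, 3, 2). Outcome 4-vectors are always indexed
(CC, CD, DC, DD), first letter the focal player's move; a single
`flip_outcome` re-encodes an outcome from the co-player's perspective
(CD ↔ DC). The match engine draws two uniforms per round from one seeded
generator — focal's draw before the co-player's — regardless of whether a
policy is stochastic, so records are bitwise reproducible and the random
stream does not depend on policy type. `simulate_outcome_counts` consumes
the identical stream and is tested to agree with the full engine round
for round; it exists so that million-round frequency estimation does not
materialize round logs.

## Zero-determinant algebra

A strategy is constructed from (ℓ, χ, φ) as
p̃ᵢ = φ[(S_X,ᵢ − ℓ) − χ(S_Y,ᵢ − ℓ)] and certified by solving the
4-equation, 3-unknown system p̃ = α·S_X + β·S_Y + γ·1 by least squares.
Certification by residual (max absolute misfit, default tolerance 1e−6)
was chosen over the determinant identity because it yields a quantitative
distance-from-ZD; the Press–Dyson determinant form serves as an
independent classification oracle in the test suite only. The reported
relation is s_X − ℓ = χ(s_Y − ℓ) with ℓ = −γ/(α+β) and χ = −β/α; both are
`None` when their denominators vanish (tit-for-tat has α + β = 0: it
enforces s_X = s_Y at every baseline). Completion of a strategy with one
unknown entry appends the entry to the unknowns, making the system square;
a singular system (no unique completion) and a solution outside [0, 1] are
distinct errors.

Probabilities printed to three decimals are stored as exact rationals
(0.692 = 9/13, 0.538 = 7/13, 0.182 = 2/11, 0.364 = 4/11); decimal input
within 5e−4 of a fraction with denominator ≤ 13 snaps to it in the
`from_decimals` constructor so downstream payoff identities are exact.
Probability bounds are the closed interval [0, 1] with no epsilon slack.

Long-run outcome distributions solve the balance equations of the 4-state
outcome chain when the stationary vector is unique (rank test at 1e−10);
reducible chains — which arise from deterministic entries — fall back to
the Cesàro average started from the two opening moves, computed by a
doubling recursion (C₂ₙ = (Cₙ + MⁿCₙ)/2, 60 doublings). The method used
is recorded on the returned distribution. The first-round move of a
constructed strategy follows the baseline: defect at ℓ = P, cooperate
above it.

## Expression policy

The two orientations differ only after mutual cooperation and after the
counterpart exploits the participant (joy/regret swapped); anger after
being exploited and neutral after mutual defection are shared. Outcomes
are encoded from the counterpart strategist's perspective before lookup,
and no expression precedes round one. A property test asserts the
orientations are indistinguishable on any round sequence containing only
CD/DD outcomes.

## Synthetic cohorts

The generator emulates a 2 × 2 between-subjects experiment (strategy ×
emotion orientation), default 85 participants per cell and 20 rounds. The
counterpart side is exact: moves follow the cell's ZD strategy, displays
follow its orientation. The participant side is a logistic memory-one
model with covariates (see `cohort.py` docstrings for the formula); the
model is a generative convenience, not a cognitive theory — its only
contract is to reproduce the qualitative structure the statistical tests
probe. All coefficients live in config, not code.

Default coefficients were calibrated once, by Monte-Carlo sweep, to a
strategy partial η² of ≈ 0.2 on cooperation rate at the default cell
size, with the emotion effect an order of magnitude smaller and confined
to generosity cells (b_emo_ext = 0 by construction), first-round
cooperation high, and an end-game drop. Expectation ratings use a 0–100
scale (the response format is an open design choice; a continuous slider
scale is assumed) and are a clipped linear function of the counterpart's
realized cooperation frequency, an inference-from-strategy loading, the
display orientation, and Gaussian noise. Self-reports are drawn from a
softmax whose joy score rises with the participant's round payoff.
Post-task ratings (mental demand, genuineness) are clipped-rounded
normals on a 1–7 scale, genuineness higher under generosity.

**Mediator endogeneity.** Because ZD counterparts reciprocate, any
mediator built from realized counterpart behavior is endogenous: the
participant's own cooperation causes counterpart cooperation, which
inflates the mediator→outcome path and produces a suppression pattern
(large negative indirect, positive direct) in the mediation analysis of
default cohorts. This is a real property of such designs, not an
artifact. The `CohortConfig.mediation_chain()` scenario therefore drives
expectations mostly from the condition itself (exogenous given condition)
with only a small realized-history loading, and routes behavior through
the expectation (b_expect); on such cohorts the mediation analysis
recovers a clean chain — indirect CI excluding zero, direct CI covering
zero — which is what the recovery tests assert. Clipping at the 0 floor
of the rating scale was itself a measurable bias source and the scenario
keeps ratings off the floor.

Per-participant aggregates enter the analyses: cooperation rate, mean
expectation, and the proportion of rounds each emotion was reported (the
joy mediator is a proportion; the natural unit for between-subject
ANOVAs and mediation).

## Statistical pipeline

* **Factorial ANOVA**: Type III sums of squares via model comparison
  under sum-to-zero effects coding (cells may be unbalanced; Type III
  matches the common practice of the commercial packages used for such
  studies). Bonferroni post-hocs multiply raw p by the number of
  comparisons, capped at 1. Cross-checked in tests against statsmodels
  and a textbook balanced decomposition at 1e−10.
* **Planned contrast**: t = Σwᵢmᵢ / √(MSE·Σwᵢ²/nᵢ) on cell means with the
  triangular "synergistic" weighting (+3, −1, −1, −1) by default; the
  error term defaults to the omnibus MSE with df = N − k. The df policy
  is exposed rather than guessed because published contrast df are not
  always derivable from the obvious error-term choices.
* **t tests**: pooled variance; effect size r = √(t²/(t²+df)).
* **Mixed (split-plot) ANOVA**: between effects are tested on subject
  means (Type III); within effects project responses on orthonormal
  within-contrasts and compare hypothesis to residual SSCP traces —
  algebraically the univariate split-plot F. Greenhouse–Geisser ε comes
  from the pooled residual covariance of contrast scores
  (ε = tr(Σ)²/((k−1)tr(Σ²)), floored at 1/(k−1)); the Huynh–Feldt
  adjustment ε̃ = ((df_e+1)(k−1)ε̂ − 2)/((k−1)(df_e − (k−1)ε̂)) with
  df_e = N − g reduces to the classic single-group formula at g = 1 and
  is capped at 1. Corrected df are ε times the uncorrected df. Missing
  within-cells raise (no imputation). k = 2 forces ε = 1.
* **Multiple mediation**: OLS paths (a per mediator; b and the direct
  effect from one outcome model containing all mediators), indirect
  = a·b, and the exact identity total = direct + Σ indirect. CIs are
  percentile bootstrap (default 5,000 resamples of participants, seeded;
  percentile rather than BCa because the simpler interval is the
  conservative default when the flavor is unspecified). The bootstrap is
  vectorized via batched normal equations in chunks of 1,000 resamples.
  The condition coding is explicit (caller chooses which level is 1);
  effects are reported signed under that coding. Rank-deficient mediator
  sets raise an error naming the offending mediators.
* **Power**: smallest total N such that a fixed-effects F test with
  noncentrality λ = f²·N, the stated numerator df, denominator df
  N − groups, reaches the target power at α — a direct scan of the
  noncentral F distribution.

p-values always come from exact F/t distributions.

## Problem sizes in the test suite

Stochastic validation uses: 10⁶-round simulations against the analytic
stationary distributions (20 random strategy pairs, 3 Monte-Carlo SE);
100 random opponents for the enforced-relation identities (tolerance
1e−6); 200 replicates for null bootstrap-CI coverage; 250 null cohorts
(30/cell) for type-I-error calibration of the ANOVA and planned
contrast; 50 cohorts each for mediation recovery and for power of the
calibrated strategy effect; and 100 null cohorts (200/cell) for the
generator's own type-I contract. These sizes put Monte-Carlo error
comfortably inside the asserted bands while keeping the default test run
at a few minutes on one CPU.

## Known limitations

* The participant model is a logistic memory-one device; it does not
  model learning, beliefs about end-game, or individual strategy types,
  so passing tests demonstrate properties of the pipeline, not of human
  behavior. Effect sizes measured on synthetic cohorts are calibration
  targets, not predictions.
* The mediation machinery is OLS-based and inherits OLS causal caveats;
  with endogenous mediators (see above) the "direct" estimate is not a
  causal direct effect.
* The mixed ANOVA requires complete round data per participant.
* Strategies with memory beyond one round, population/evolutionary
  dynamics, and continuous-action games are out of scope.
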