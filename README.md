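# coopsignal

Tools for studying how **behavioral strategy** and **emotion signalling**
jointly shape cooperation in the iterated prisoner's dilemma — built around
the zero-determinant (ZD) strategy algebra, a reproducible match engine, an
outcome-contingent expression policy, a synthetic-participant cohort
generator, and the complete statistical pipeline such behavioral
experiments use.

## The science

In the iterated prisoner's dilemma two players repeatedly choose to
cooperate (C) or defect (D); per round, mutual cooperation pays R each,
mutual defection P, and unilateral defection T to the defector and S to
the cooperator, with T > R > P > S (here T=7, R=5, P=3, S=2). A
*memory-one* strategy is a vector p = (p_CC, p_CD, p_DC, p_DD) of
cooperation probabilities conditioned on the previous outcome, plus an
opening move. Press and Dyson showed that if the shifted vector
p̃ = (p₁−1, p₂−1, p₃, p₄) lies in span{S_X, S_Y, 1} — with
S_X = (R, S, T, P) and S_Y = (R, T, S, P) the two players' payoff
vectors — the strategist unilaterally enforces a linear relation

    α·s_X + β·s_Y + γ = 0   ⇔   s_X − ℓ = χ·(s_Y − ℓ)

between the long-run payoffs, with baseline ℓ = −γ/(α+β) and slope
χ = −β/α. *Extortion* anchors the relation at ℓ = P (the strategist's
surplus over mutual defection is χ-fold the co-player's); *generosity*
anchors it at ℓ = R. The package ships the two study strategies with
exact rational entries:

* extortion (χ = 3): p = (9/13, 0, 7/13, 0) ≈ (0.692, 0, 0.538, 0), opens D;
* generosity (χ = 3): p = (1, 2/11, 1, 4/11) ≈ (1, 0.182, 1, 0.364), opens C.

On top of the game layer, counterparts display outcome-contingent facial
expressions under a *cooperative* orientation (joy after mutual
cooperation, regret after exploiting the partner, anger after being
exploited, neutral otherwise) or a *competitive* one (joy and regret
swapped on exactly those two outcomes). The statistical layer implements,
from first principles, everything needed to analyze a 2 × 2
(strategy × emotion) between-subjects experiment with 20 rounds per
participant: Type III factorial ANOVA with Bonferroni post-hocs, partial
η², planned single-df contrasts, pooled t tests with r effect sizes, a
split-plot mixed ANOVA with Greenhouse–Geisser/Huynh–Feldt sphericity
correction, bootstrap multiple mediation, and noncentral-F sample-size
planning.

Because the statistical pipeline needs data to chew on, the
`coopsignal.cohort` module generates synthetic participant cohorts whose
trial tables carry the qualitative structure such experiments exhibit:
high first-round cooperation with an end-game drop, a strategy effect
much larger than the emotion effect, an emotion effect confined to
generous counterparts, and condition effects carried by expectation
ratings and reported joy.

## Worked example

```python
from coopsignal.cohort import CohortConfig
from coopsignal.io import RunConfig, run_experiment

res = run_experiment(RunConfig(cohort=CohortConfig(seed=2024),
                               n_boot=2000, out_dir="demo"))
```

which, on the default study-shaped cohort (4 × 85 participants, 20
rounds), prints/stores among others:

```
strategy:         F(1, 336) = 76.09, p = 1.3e-16, partial eta^2 = 0.185
emotion:          F(1, 336) = 11.14, p = 0.00094, partial eta^2 = 0.032
planned contrast: t(336) = 8.74, p = 1.1e-16
emotion t test [generosity]: t(168) = 4.03, p = 8.3e-05, r = 0.297
emotion t test [extortion]:  t(168) = 0.21, p = 0.835,   r = 0.016
round effect: F(18.33, 6160.19) = 14.00, p_HF = 5.4e-43 (eps_HF = 0.965)
strategy mediation: total = -0.183, direct = 0.315,
                    indirect via expectation = -0.407 [95% CI -0.473, -0.341]
```

Reading: cooperation responds far more to the counterpart's strategy than
to its emotion displays; the emotion effect appears only under the
generous strategy; cooperation varies across rounds (Huynh–Feldt
corrected df); and the strategy effect on cooperation is carried by
participants' expectations of counterpart cooperation (with extortion
coded 1, the indirect path through lowered expectations is negative; the
positive direct estimate reflects the well-known suppression that arises
because reciprocating counterparts make the expectation mediator
endogenous — see `docs/methods.md`).

The same functionality is exposed on the command line:

```
coopsignal simulate --seed 3 --out sim/
coopsignal analyze --trials sim/trials.csv --out results/
coopsignal zd verify --strategy extortion.yml --json
coopsignal zd complete --strategy partial.yml
coopsignal power --f 0.2 --alpha 0.05 --power 0.95 --groups 4 --df1 1
coopsignal report --seed 11 --out run/
```

## Layout

| module                 | contents                                                      |
|------------------------|---------------------------------------------------------------|
| `coopsignal.game`      | stage game, outcome encoding, iterated-match engine           |
| `coopsignal.zd`        | ZD construction, certification, completion, stationary payoffs|
| `coopsignal.emotions`  | outcome-contingent expression policies                        |
| `coopsignal.cohort`    | synthetic cohort generator                                    |
| `coopsignal.stats`     | ANOVA, contrasts, mixed ANOVA, mediation, power               |
| `coopsignal.io`        | CSV/YAML/JSON formats, end-to-end orchestration               |
| `coopsignal.cli`       | `coopsignal` command-line interface                           |

See `docs/methods.md` for the models, assumptions, numerical choices, and
known limitations.
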