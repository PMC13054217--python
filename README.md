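# woundcdss

Safety-first treatment decision support for pressure ulcers, plus the full
statistical apparatus to evaluate it in a randomized AB/BA crossover study.

## The problem

In many settings pressure ulcers are managed by general internists rather than
wound-care specialists, and guideline adherence is poor. A simple
decision-support rule set can walk a non-specialist through a handful of
questions about a wound — acute or chronic phase, depth, necrotic tissue,
exudate, infection, undermined pockets, granulation — and recommend one
ointment and one wound dressing, with a hard safety layer: **an occlusive
(moisture-retaining) dressing is never recommended for an infected wound or a
pocket containing necrotic tissue**, because sealing such wounds risks abscess
formation.

This package provides:

- **`woundcdss.state`** — the finite wound-state space (300 valid states over
  8 categorical attributes, a reduction of the DESIGN-R assessment axes) and
  the two 6-option treatment vocabularies.
- **`woundcdss.engine`** — a generic, auditable decision-tree interpreter; the
  clinical logic itself is data (`data/decision_tree.json`), exhaustively
  validated for totality and safety.
- **`woundcdss.scoring`** — strict exact-match scoring of clinician responses
  against the 10-question answer key (`data/answer_key.json`) and raw
  phase-level correct-response rates.
- **`woundcdss.design`** — permuted-block 1:1 randomization and assembly of
  the long-format crossover analysis table (one row per clinician × question;
  28 clinicians → 280 rows).
- **`woundcdss.gee`** — a from-scratch GEE estimator for clustered binary
  outcomes (binomial variance, logit link, exchangeable working correlation,
  robust sandwich covariance, Wald inference), organised statsmodels-style as
  a `BinaryGEE` model whose `fit()` returns a `GEEResults` object.
- **`woundcdss.simulate`** — a random-intercept logistic simulator of
  clinician panels, with Gauss–Hermite marginalization so simulation studies
  target the population-averaged estimand a GEE actually estimates.

## The model

The evaluation fits the marginal logistic model

```
logit P(correct_ij = 1) = β0 + β1·treatment_ij + β2·period_ij + β3·sequence_i
```

for response *j* of clinician *i*, with responses clustered within clinician
under an exchangeable working correlation α, estimated by generalized
estimating equations with the robust (sandwich) covariance. `exp(β1)` is the
adjusted odds ratio (aOR) for answering correctly with decision support
versus without, adjusted for period (learning) and sequence (carryover)
effects of the crossover.

## Worked example

Ask for a recommendation for a deep chronic ulcer covered with dry black
necrotic tissue and minimal exudate:

```bash
woundcdss recommend --phase chronic --depth deep --necrosis black_dry --exudate minimal
```

```json
{
  "ointment": {"code": 1, "label": "silver sulfadiazine"},
  "dressing": {"code": 5, "label": "hydrogel", "occlusive": true},
  "trace": ["phase", "chronic_infection", "pocket", "necrosis",
            "black_exudate", "leaf_black_dry"]
}
```

The trace is the audit trail through the tree: the wound is chronic, not
infected, not pocketed, black-necrotic with minimal exudate, so conservative
autolytic debridement (hydrogel over silver sulfadiazine) is recommended.

Simulate a 28-clinician crossover trial and analyse it:

```python
import woundcdss as w

params = w.SimulationParams(n_participants=28, p_correct_control=0.15,
                            p_correct_intervention=0.55,
                            random_intercept_sd=1.0, seed=7)
table = w.simulate_trial(params)                      # 280 rows
print(w.analyze_crossover(table, outcome="ointment").summary())
```

```
outcome    intervention %  control %          aOR (95% CI)       P
ointment             39.3       15.7      3.88 (2.04-7.39)   <.001

Binary GEE (logit link, exchangeable working correlation)
clusters: 28   observations: 280   alpha: 0.0941   iterations: 6   converged: True
------------------------------------------------------------------------------
                  coef   robust se        z    P>|z|        OR    [0.025    0.975]
intercept      -1.7618      0.3826   -4.604    <.001     0.172     0.081     0.364
treatment       1.3563      0.3284    4.131    <.001     3.882     2.040     7.389
period          0.5454      0.3284    1.661     .097     1.725     0.906     3.284
sequence       -0.6053      0.3743   -1.617     .106     0.546     0.262     1.137
------------------------------------------------------------------------------
```

The raw correct-response rates (39.3% with support vs 15.7% without) are
plain proportions; the aOR of 3.88 is the treatment effect adjusted for
clustering, period and sequence. Note the attenuation relative to the
generating conditional odds ratio — a GEE estimates the population-averaged
effect (see `woundcdss.marginalize`).

The same pipeline is available from the shell:
`woundcdss simulate … | woundcdss assemble … | woundcdss analyze …`
(see `woundcdss --help`).

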