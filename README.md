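# epicmap

Map **EPIC** (Expanded Prostate Cancer Index Composite) scores to
**EQ-5D-3L health utilities** — and rebuild, stress-test, or re-estimate the
whole mapping workflow on synthetic cohorts.

## Why

Prostate-cancer trials usually collect EPIC, a disease-specific
patient-reported outcome with four 0–100 domains (Urinary, Bowel, Sexual,
Hormonal) and ten function/bother sub-domains, but often no preference-based
measure. Cost-utility analyses, however, need utilities — EQ-5D index
values anchored at 1 (full health) and 0 (dead) — to compute
quality-adjusted life-years. A *mapping algorithm* (crosswalk) is a
regression that predicts the EQ-5D utility a patient would have reported
from the EPIC scores they did report.

`epicmap` is aimed at health-economics and outcomes researchers. It ships:

- **Scoring** — a generic additive EQ-5D-3L tariff engine
  (`utility = 1 + Σ level decrements + Σ extra terms` over the 3⁵ = 243
  describable states; value sets are JSON data, validated on load), and the
  linear Likert → 0–100 EPIC transform.
- **Published mapping algorithms** as built-ins, at full printed precision:
  the parsimonious reduced model

  ```
  EQ5D = 0.248541 + 0.000748·UF + 0.001134·UB + 0.000968·HF + 0.004404·HB
         − 0.376487·Zubrod + 0.003562·UF·Zubrod
  ```

  and the 26-term full model `full_6i` (all ten sub-domains, an age cubic,
  race, Zubrod, ten score×Zubrod products, PSA ≥ 4). Predictions are
  deliberately *not* clipped at 1 by default; clipping is an explicit
  option for QALY pipelines.
- **The model-development battery** — design-matrix construction for six
  specification groups (domains vs sub-domains, with/without demographic
  and clinical covariates, polynomial and interaction terms), OLS,
  an upper-censored **Tobit** maximum-likelihood estimator
  (`y = min(y*, 1)`, `y* ~ N(Xβ, σ²)`), a **two-part** model (logistic
  ceiling probability × below-ceiling OLS, recombined as
  `p·1 + (1−p)·ŷ₂`), and SAS-style forward stepwise selection with entry/
  stay thresholds of 0.25 — all as scikit-learn-style estimators.
- **Validation machinery** — seeded 70/30 splits, k-fold cross-validation
  with PRESS-based RMSE (`RMSE = √(Σ fold PRESS / n)`), MAE, external
  validation of frozen models, RMSE ranking, Bland–Altman limits of
  agreement, and diagnostic plots.
- **A calibrated synthetic cohort generator** — a Gaussian copula tying a
  ceiling-inflated bimodal utility margin (55 % mass at exactly 1, a Beta
  component on [0.28, 1) peaking near 0.8, overall mean 0.90 / SD 0.13) to
  censored-normal EPIC margins with the published means, SDs, and
  utility–score Pearson correlations, plus trial-like demographics.

## Worked example

```python
import epicmap as em
from epicmap.estimation import DesignSpec
from epicmap.validation import (kfold_cross_validate, external_validate,
                                rank_models, split_estimation_validation)

# a synthetic trial cohort with the calibrated marginals
cohort = em.generate_cohort(n=1092, seed=1)
split = split_estimation_validation(cohort, fraction=0.70, seed=1)
est = cohort.loc[split.estimation_ids]      # 765 records
val = cohort.loc[split.validation_ids]      # 327 records

# compare functional forms on the domain-only specification (group 1)
spec = DesignSpec(group=1)
reports = [kfold_cross_validate(est, spec, form=f, seed=1, label=f"group1-{f}")
           for f in ("ols", "tobit", "two_part")]
for r in rank_models(reports):
    print(r.label, r.rendered_rmse(), r.rank)

# apply the published reduced algorithm to one patient
model = em.builtin_reduced_model_6()
rec = em.predict_utility(model, dict(epic_uf=85, epic_ub=70,
                                     epic_hf=90, epic_hb=95, zubrod=0))
print(rec.predicted_utility)

# external validation of the frozen model on the held-out 30 %
ext = external_validate(model, val)
print(ext.rendered_rmse(6), ext.n)
```

prints

```
group1-ols 0.10217 1
group1-two_part 0.10238 2
group1-tobit 0.11644 3
0.8970009999999999
0.107814 327
```

OLS ranks first: on a ceiling-inflated mixture the latent-normal Tobit is
misspecified and its truncated predictions concentrate too close to 1,
while OLS targets the conditional mean directly. The mapped utility
0.897 is the literal linear predictor of the printed equation; the
six-decimal external RMSE is the frozen model's error on 327 unseen
records.

The same workflow is scriptable: `epicmap simulate | score | map | fit |
validate`, each emitting a JSON run manifest (`--seed`, parameters, paths,
version) next to its output.

### A note on value sets

The tariff engine is value-set-agnostic. The packaged
`us3l_synthetic.json` is a clearly-labelled **synthetic stand-in** with
the structure of the published US valuation (it anchors full health at
1.0, scores the worst state at −0.108, and puts mild states near 0.8);
for production scoring load a transcribed published value set via
`epicmap.load_value_set(path)`.

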