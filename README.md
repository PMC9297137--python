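# foodtract

Census-tract food-environment analysis from geotagged short texts.

Public-health researchers identify *food deserts* — census tracts that are
both **low-income** and **low-access** under the USDA Food Access Research
Atlas criteria — from surveys, store assessments and GIS data. `foodtract`
implements the complementary *infodemiology* route: residents' own
geotagged posts about food are mined for tract-level signals of the local
food environment. The package is for biostatisticians and computational
epidemiologists who want a tested, reproducible implementation of this
pipeline, together with a synthetic-data generator that makes every stage
verifiable without access to any social-media corpus.

## What it computes

1. **Ingestion.** Posts are filtered to those that are geolocated,
   non-promotional (token-level hashtag blocklist: `#jobs`, `#hiring`,
   `#ad`, `#job`) and mention at least one food keyword.
2. **Food matching.** Greedy longest-first phrase matching against a food
   lexicon (keyword → healthy/unhealthy/fast-food category + per-100 g
   nutrient vector): "Burger King" is matched before "burger", and consumed
   tokens are never reused. Per post, category counts and available-case
   nutrient means are recorded.
3. **Sentiment.** A word-polarity lexicon scores each post by the summed
   ±1 polarities of its tokens; the sign labels the post and raises up to
   one flag per mentioned food category (e.g. `healthy_pos`).
4. **Tract assignment.** Point-to-bounding-box containment (smallest-area
   box wins, deterministic tie-breaks), or true point-in-polygon.
5. **Features + label.** Per tract: 6 sentiment shares, 3 mean mention
   counts, 17 nutrient means and 2 category-restricted calorie means (28
   features), merged with 12 SES covariates and labeled
   `food desert = low-income AND low-access` (all USDA boundaries
   inclusive).
6. **Association screen.** One adjusted OLS per feature,

   y<sub>feature</sub> = β₀ + β<sub>FD</sub>·x<sub>FD</sub> + β₁·SES₁ + … + β₁₂·SES₁₂ + ε,

   reporting β<sub>FD</sub>, SE, the two-sided *t* p-value (df = n − 14)
   and R²; features with raw p < α form the "significant set".
7. **Classification benchmark.** Five feature sets (SES baseline; +nutrition;
   +sentiment; +both; +significant set) × four learners (AdaBoost stumps,
   gradient boosting, logistic regression, stacked ensemble), with
   stratified 70:30 split, training-only min-max scaling and median
   imputation, 5-fold CV hyperparameter selection, and held-out AUC
   (midrank Mann–Whitney).
8. **Synthetic data.** Unit-square tracts, SES tables with an exactly
   controlled food-desert count, curated lexicons, and tweet corpora with
   signed effects implanted at the sampling level (+healthy-positive
   share, +fast-food-positive share, +unhealthy mentions, +cholesterol,
   −potassium in desert tracts), so the full chain must transmit the
   signal. See `docs/methods.md` for the model and its limitations.

## Worked example

```python
from foodtract import SplitConfig, SyntheticConfig, run_synthetic_study

cfg = SyntheticConfig(n_tracts=800, seed=11)
res = run_synthetic_study(
    cfg,
    split=SplitConfig(seed=11),
    methods=("gradient_boosting", "logistic_regression"),
    models=(1, 3),
)
print(res.benchmark.round(3).to_string(index=False))
```

prints

```
             method  model_id   auc  seed  delta_vs_baseline
  gradient_boosting         1 0.894    11              0.000
logistic_regression         1 0.780    11              0.000
  gradient_boosting         3 0.934    11              0.040
logistic_regression         3 0.853    11              0.073
```

(see `examples/05_classification_benchmark.py`). Model 1 classifies
tracts from the 12 SES covariates alone; model 3 adds the six tweet
sentiment shares. The positive `delta_vs_baseline` means the tweet-derived
sentiment features carry predictive signal about desert status beyond
demographics — the direction the analysis is designed to detect. The
`examples/` directory holds one short script per capability (lexicons and
matching, filters and sentiment, tract features and labels, the
association screen, the benchmark, and file round-trips).

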