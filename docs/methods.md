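# Methods

`foodtract` turns a corpus of geotagged short posts into census-tract-level
food-environment features, labels tracts as food deserts, screens each
feature for an adjusted association with desert status, and benchmarks
whether the tweet-derived features improve food-desert classification over
a demographics-only baseline. This note records the model, the knobs that
matter, the numerical conventions, and what the synthetic data can and
cannot show.

## Pipeline model

**Ingestion.** A post enters the analysis only if (i) it carries GPS
coordinates in valid WGS84 range, (ii) it contains no promotional hashtag
token (default blocklist `#jobs`, `#hiring`, `#ad`, `#job`; matching is on
whitespace-split lowercased tokens, so `#advice` is never removed by
`#ad`), and (iii) it matches at least one food keyword. The three filters
are idempotent, and the geolocation and promotional filters commute because
they inspect disjoint fields.

**Keyword matching.** The food lexicon maps lowercase phrases to a category
(healthy / unhealthy / fast food) and a per-100 g nutrient vector (17
fields; fatty acids split into saturated/trans/unsaturated). Matching is
greedy longest-first over a canonical token stream (lowercased; URLs and
@-mentions removed; `#` stripped; split on non-alphanumeric boundaries):
all k-word keywords are matched before any (k−1)-word keyword, consumed
tokens are never reused, occurrences within a level are consumed left to
right, and a single-word keyword also matches a token bearing one trailing
plural "s" (a config switch disables this). The left-to-right rule plus an
exact-before-plural preference makes the matcher total and deterministic; a
brute-force placement-enumeration oracle verifies it on random cases.
Every non-overlapping occurrence counts (mention *counts*, not indicators).

**Per-tweet scoring.** Category counts are tallied and nutrients are
averaged available-case over matched items: a nutrient is missing from the
tweet mean only when no matched item carries it. This matters because
restaurant-name entries carry no nutrient profile at all — a fast-food
mention must not zero out the nutrient mean. Calorie means restricted to
healthy and to unhealthy matches are kept separately.

**Sentiment.** Each token found in a word-polarity lexicon contributes ±1;
the sign of the sum labels the tweet positive/negative/neutral. There is no
negation or intensity handling — the method is a plain lexicon sum, and
repeated words count each occurrence. The full token stream is scored,
including words inside matched food phrases. A tweet raises at most one
flag per mentioned category (`healthy_pos`, …, `fastfood_neg`); neutral
tweets raise none but stay in every denominator.

**Tract assignment.** The default assignment is point-to-bounding-box, the
cheap rectangle test; real adjacent tracts have overlapping envelopes, so
among containing boxes the smallest-area box wins, with lexicographic
tract-id as the final tie-break — a total, deterministic rule. Polygon
mode (true point-in-polygon with a bbox prefilter) is the geometrically
correct alternative; on non-overlapping tracts the two agree. Boundary
points count as inside; a half-open convention would silently drop
grid-aligned synthetic points. Bulk assignment uses an STR packed tree and
is verified against the per-point rule.

**Tract features.** One row per tract with ≥1 mapped food-related tweet:
six sentiment-share percentages (denominator = *all* the tract's food
tweets, neutral included), three mean mention counts, 17 available-case
nutrient means, and the two category-restricted calorie means — 28
features. SES covariates (12 fields: race/ethnicity shares, owner
occupancy, poverty, housing units, households, median family income,
median age, population) join by inner merge; tracts lacking SES are
dropped with a logged count.

**Food-desert label.** USDA Food Access Research Atlas style: low income =
poverty ≥ 20%, or median family income ≤ 80% of the state median, or —
only when a metro median is supplied — ≤ 80% of the metro median; low
access = ≥ 500 residents or ≥ 33% of residents far from a supermarket
(access is consumed as an input, measured at the appropriate 1-/10-mile
distance; it is never derived from store locations here). All boundaries
are inclusive. Food desert = low income AND low access; the label is
monotone in poverty and in the access measures.

## Association screen

For each feature y, one OLS fit of
`y = b0 + b_FD·FD + b1·SES1 + … + b12·SES12 + e`, reporting `b_FD`, its
standard error, the two-sided t-test p-value on n − 14 df, and R².
The fit is a QR solve with covariance `(R⁻¹R⁻ᵀ)·s²`; an independent
statsmodels fit agrees to 1e−8 relative tolerance in tests. Missing
feature values (tracts whose tweets contributed no value for a nutrient)
are dropped listwise per feature, with ≥ 20 complete rows required.
Conventions: constant y ⇒ (β=0, R²=0, p=1); a rank-deficient design raises
an error naming the collinear columns. SES controls enter untransformed —
min-max scaling belongs to classification only — and no multiple-testing
correction is applied; the report carries raw p-values. The "significant
set" (raw p < α, default α = 0.05) feeds classification model 5.

## Classification benchmark

Feature sets: (1) 12 SES covariates (baseline); (2) SES + the 22
nutrition-side features (mention counts and nutrient means — the mention
counts sit with nutrition, not sentiment, since they carry no polarity);
(3) SES + the 6 sentiment shares; (4) SES + both; (5) SES + the screen's
significant set. Rows are split 70:30 stratified by label; 5 stratified
folds over the training rows drive hyperparameter selection by mean CV
AUC over small fixed grids (AdaBoost stumps, 50/100/200 rounds; gradient
boosting depth 1–3 × 100/200 rounds; logistic L2 with C ∈ {0.1, 1, 10}).
Missing feature cells are imputed with training-set medians, then features
are min-max scaled with training-set minima/maxima only (a constant
training column maps to zeros; test values are not clipped). The stacked
ensemble fits the three base methods, uses their out-of-fold training
scores as meta-features for a logistic meta-learner, and at test time
feeds full-train refits of the bases into it. Test AUC on the held-out 30%
is the reported metric (CV is for tuning only; AUC is computed from
midranks, i.e. Mann–Whitney with half credit for ties, and verified
against O(n²) pair counting). No class re-weighting or resampling is done;
class imbalance is addressed only through the metric choice. Everything is
deterministic given the split seed.

Where the split-then-scale order was genuinely open, the train-only choice
was made and asserted by a leakage test; likewise stratification is a
design choice made because ~7.5% prevalence makes unstratified 5-fold CV
risk single-class folds.

## Synthetic data: what it emulates and what it does not

The generator emulates the five inputs: unit-square tracts on a grid
(disjoint, so bbox and polygon assignment agree and overlapping-bbox
tie-breaks are exercised only by dedicated unit tests), an SES table drawn
near published tract-level means (income ~ N(82 371, 42 680²) truncated,
poverty, demographics, etc.), a 42-entry food lexicon spanning the three
categories (with the "burger king"/"burger" longest-first stress pattern,
and fast-food entries carrying no nutrients), a 60-word polarity lexicon,
and a geotagged corpus with per-tract counts 1 + NegBin(mean 3.8, shape
1.3) (median ≈ 4 tweets/tract). Exactly `round(n_tracts × fraction)`
tracts (default fraction 0.0752) receive SES/access values satisfying the
USDA criteria — the construction is round-tripped through the labeler —
and a further ~18% of tracts are low-income but high-access, so income
alone does not identify deserts and the SES-only classifier is informative
but imperfect.

Effects are implanted at the sampling level so every stage must transmit
them: desert-tract tweets shift category probability toward unhealthy
(+0.15), draw unhealthy keywords ∝ exp(1.2·z_cholesterol) and healthy
keywords ∝ exp(−1.2·z_potassium), and have their positive-sentiment
probability raised by +0.38 when a healthy food and +0.45 when a fast-food
restaurant is mentioned. Cholesterol and potassium anchors are kept
roughly uncorrelated within the unhealthy category so the cholesterol tilt
does not drag potassium with it. The magnitudes were fixed once by an a
priori power calculation targeting z ≈ 4–6 per implanted effect at 1000
tracts under the configured tweet volume, so the five-signed recovery
property holds with high probability; `SyntheticConfig.null()` zeroes all
five knobs for calibration runs. Promotional (`#hiring` …) and
non-geolocated posts are injected at 4%/5% purely to exercise the filters.

What passing on this data does *not* show: the text is templated filler —
no misspellings, sarcasm, negation, named entities, or city-specific
geography — so matcher and sentiment accuracy on real language is not
evidenced; tract geometry is idealized; SES covariates are mutually
independent apart from the label construction, unlike real census data;
and effect sizes are far larger than the small real-data associations.
The synthetic study validates the *machinery* (filters, matcher,
aggregation, estimator calibration, benchmark plumbing), not real-world
effect sizes or AUCs.

## Problem sizes used in the shipped checks

The packaged verification runs use sizes chosen to make their Monte Carlo
bands tight while staying desk-scale: label-construction worked example at
3978 tracts; matcher oracle on 10 000 random texts (≤ 12 tokens, ≤ 6
keywords); AUC oracle on 1000 instances (≤ 50 rows); OLS oracle on 100
random designs plus 200-replicate CI coverage at n = 500; null screen
calibration on replicates of a 600-tract null configuration; signed
recovery over replicates at 1000 tracts; benchmark direction checks at
600–1000 tracts. Null-calibration rejection rates are averaged over the 28
features and replicates; individual per-feature rates at these sizes carry
Monte Carlo noise of a few percentage points.

## Known limitations

- The promotional blocklist is three published examples plus `#job`; real
  promotional language is far broader.
- Bounding-box assignment misattributes points in concave/overlapping real
  tract geometry; polygon mode exists but real GeoJSON tract files can
  carry invalid rings that the loader rejects rather than repairs.
- Lexicon sentiment has no negation ("not good" scores +1), and sentiment
  words inside matched food phrases still score.
- The screen fits 28 separate OLS models with raw p-values; with real
  spatially correlated data the error independence assumption would be
  suspect, and no spatial or mixed-effects structure is modeled.
- Available-case nutrient means make tract nutrient features depend on
  which items carry profiles; tracts whose tweets mention only restaurant
  names have missing nutrient features and rely on median imputation in
  classification.
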