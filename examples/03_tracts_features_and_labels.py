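"""Generate a synthetic study area, map tweets to tracts and label deserts.

Tracts are unit squares on a grid; each geotagged post is assigned to the
tract whose bounding box contains it, per-tweet scores are aggregated to
28 tract-level features, SES covariates are merged, and each tract is
labeled a food desert iff it is low-income AND low-access (USDA criteria).
"""

from foodtract import (
    SyntheticConfig,
    generate_dataset,
    run_pipeline,
    sentiment_lexicon_from_frame,
    tracts_from_geojson,
)

cfg = SyntheticConfig(n_tracts=150, seed=42)
ds = generate_dataset(cfg)
result = run_pipeline(
    ds.to_corpus(),
    tracts_from_geojson(ds.tracts_geojson),
    ds.ses,
    ds.food_lex(),
    sentiment_lexicon_from_frame(ds.sentiment_lexicon),
)
table = result.analysis_table

print(f"tweets surviving filters: {len(result.corpus)} of {len(ds.tweets)} generated")
print(f"tracts with >= 1 food-related tweet: {len(table)}")
n_desert = int(table["is_food_desert"].sum())
print(f"food deserts: {n_desert} ({100 * n_desert / len(table):.2f}% of tracts)")

cols = ["tract_id", "n_tweets", "pct_healthy_pos", "mean_unhealthy_mentions",
        "mean_cholesterol", "is_food_desert"]
print("\nfirst tract rows:")
print(table[cols].head(5).to_string(index=False))
# pct_healthy_pos is the share of the tract's food tweets that mention a
# healthy food with positive sentiment; mean_cholesterol averages the
# per-item cholesterol (per 100 g) of foods mentioned in the tract.
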