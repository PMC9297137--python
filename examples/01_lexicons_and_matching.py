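"""Load the bundled synthetic lexicons and match food keywords in a post.

The matcher is greedy longest-first: multi-word keywords ("burger king",
"red velvet cake") are matched before their single-word components, and a
token can contribute to only one match.
"""

from foodtract import food_lexicon_from_frame, generate_lexicons, match_foods, score_tweet
from foodtract.ingest import Tweet
from foodtract.lexicon import validate_lexicon

food_frame, _ = generate_lexicons()
lex = food_lexicon_from_frame(food_frame)
report = validate_lexicon(lex)
print(f"lexicon: {report.n_entries} entries, by category {dict(report.category_counts)}")

text = "Craving Burger King fries tonight, or maybe red velvet cake"
matches = match_foods(text, lex)
print(f"\ntext: {text!r}")
for m in matches:
    print(f"  matched {m.keyword!r} -> {m.category} (tokens {list(m.span)})")

profile = score_tweet(Tweet("demo", text=text), matches)
print(
    f"\nper-tweet profile: {profile.n_healthy} healthy, {profile.n_unhealthy} unhealthy, "
    f"{profile.n_fastfood} fast-food mentions"
)
print(f"mean cholesterol per matched item: {profile.mean_nutrients['cholesterol']:.1f} per 100 g")
# The mean averages the items that carry a nutrient profile; the restaurant
# name ("burger king") contributes to the fast-food count but not the mean.
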