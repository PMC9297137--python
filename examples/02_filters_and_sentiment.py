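"""Apply the three corpus filters and score sentiment-by-category flags.

A post survives ingestion only if it is geolocated, non-promotional and
mentions at least one food keyword; surviving posts get a summed-polarity
sentiment score whose sign sets up to one flag per food category.
"""

from foodtract import (
    analyze_tweet,
    filter_food_related,
    filter_geolocated,
    filter_promotional,
    food_lexicon_from_frame,
    generate_lexicons,
    profile_corpus,
    sentiment_lexicon_from_frame,
)
from foodtract.ingest import Tweet, TweetCorpus

food_frame, senti_frame = generate_lexicons()
food_lex = food_lexicon_from_frame(food_frame)
senti_lex = sentiment_lexicon_from_frame(senti_frame)

corpus = TweetCorpus(
    (
        Tweet("1", text="I love this kale salad", latitude=0.5, longitude=0.5),
        Tweet("2", text="Now #hiring line cooks, burger experience a plus", latitude=0.5, longitude=0.6),
        Tweet("3", text="gross soggy fries at the game", latitude=0.2, longitude=0.9),
        Tweet("4", text="new phone day"),  # not geolocated
        Tweet("5", text="traffic again"),  # no food keyword
    )
)
corpus = filter_food_related(
    filter_promotional(filter_geolocated(corpus)), food_lex
)
print("filter history:")
for note in corpus.provenance:
    print(" ", note)

profiles = profile_corpus(corpus, food_lex)
print("\nper-tweet sentiment and flags:")
for tweet, profile in zip(corpus, profiles):
    result = analyze_tweet(tweet.text, profile, senti_lex)
    raised = [name for name, on in result.flags.items() if on]
    print(f"  {tweet.id}: score {result.score:+d} ({result.label}), flags {raised}")
# Tweet 1 raises healthy_pos (healthy mention + positive score); tweet 3
# raises unhealthy_neg; the promotional and non-geolocated posts are gone.
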