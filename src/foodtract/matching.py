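"""Greedy longest-first food keyword matching and per-tweet scoring.

Multi-word keywords are matched before shorter ones so that, e.g., a text
mentioning a burger chain by its two-word name is credited to the chain
(fast-food category) rather than to the single-word keyword "burger"; the
consumed tokens are then unavailable to shorter keywords.  Per tweet, the
matches are tallied into category counts and an available-case mean
nutrient vector (the average per-100 g profile of the matched items).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Sequence, TYPE_CHECKING

from ._tokenize import tokenize
from .lexicon import FoodEntry, FoodLexicon, NUTRIENT_FIELDS

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import Tweet, TweetCorpus


@dataclass(frozen=True)
class FoodMatch:
    """One keyword occurrence: the lexicon entry plus the token span used."""

    keyword: str
    category: str
    nutrients: Mapping[str, float]
    span: tuple[int, ...]

    @classmethod
    def from_entry(cls, entry: FoodEntry, span: Sequence[int]) -> "FoodMatch":
        return cls(
            keyword=entry.keyword,
            category=entry.category,
            nutrients=entry.nutrients,
            span=tuple(span),
        )


@dataclass(frozen=True)
class TweetFoodProfile:
    """Per-tweet food matches, category counts and mean nutrient vector.

    ``mean_nutrients`` holds the available-case mean over matched items: a
    nutrient is missing from the mapping iff it is missing for every
    matched item.  ``mean_calories_healthy``/``mean_calories_unhealthy``
    restrict the calorie mean to matches of that category (None when no
    such match contributes).
    """

    tweet_id: str
    matches: tuple[FoodMatch, ...]
    n_healthy: int
    n_unhealthy: int
    n_fastfood: int
    mean_nutrients: Mapping[str, float]
    mean_calories_healthy: float | None
    mean_calories_unhealthy: float | None


def _depluralize(token: str) -> str | None:
    """One-trailing-'s' plural fallback ('burgers' -> 'burger')."""
    if len(token) > 2 and token.endswith("s") and not token.endswith("ss"):
        return token[:-1]
    return None


def match_foods(
    text: str, lex: FoodLexicon, plural_tolerance: bool = True
) -> list[FoodMatch]:
    """Find all non-overlapping food keyword occurrences in ``text``.

    The text is tokenized (case- and punctuation-insensitively) and scanned
    for keywords of the largest word count first, then progressively
    shorter ones; within one word-count level occurrences are consumed left
    to right, and a consumed token can never contribute to a second match.
    Single-word keywords optionally also match a token bearing one trailing
    plural "s".  Matches are returned in text order.
    """
    tokens = tokenize(text)
    n = len(tokens)
    consumed = [False] * n
    matches: list[FoodMatch] = []
    for k, level in lex.word_count_index.items():
        if k > n:
            continue
        start = 0
        while start <= n - k:
            span = range(start, start + k)
            if any(consumed[i] for i in span):
                start += 1
                continue
            phrase = tuple(tokens[start : start + k])
            entry = level.get(phrase)
            if entry is None and k == 1 and plural_tolerance:
                singular = _depluralize(phrase[0])
                if singular is not None:
                    entry = level.get((singular,))
            if entry is not None:
                matches.append(FoodMatch.from_entry(entry, span))
                for i in span:
                    consumed[i] = True
                start += k
            else:
                start += 1
    matches.sort(key=lambda m: m.span[0])
    return matches


def score_tweet(tweet: "Tweet", matches: Sequence[FoodMatch]) -> TweetFoodProfile:
    """Tally category counts and average the matched items' nutrients.

    Nutrient means are available-case: each nutrient is averaged over the
    matched items that carry it, and is missing only when no matched item
    does.  With zero matches all counts are 0 and every nutrient is missing.
    """
    counts = {"healthy": 0, "unhealthy": 0, "fastfood": 0}
    for m in matches:
        counts[m.category] += 1
    mean_nutrients: dict[str, float] = {}
    for name in NUTRIENT_FIELDS:
        values = [m.nutrients[name] for m in matches if name in m.nutrients]
        if values:
            mean_nutrients[name] = fmean(values)
    by_cat_calories = {}
    for cat in ("healthy", "unhealthy"):
        values = [
            m.nutrients["calories"]
            for m in matches
            if m.category == cat and "calories" in m.nutrients
        ]
        by_cat_calories[cat] = fmean(values) if values else None
    return TweetFoodProfile(
        tweet_id=tweet.id,
        matches=tuple(matches),
        n_healthy=counts["healthy"],
        n_unhealthy=counts["unhealthy"],
        n_fastfood=counts["fastfood"],
        mean_nutrients=mean_nutrients,
        mean_calories_healthy=by_cat_calories["healthy"],
        mean_calories_unhealthy=by_cat_calories["unhealthy"],
    )


def profile_corpus(corpus: "TweetCorpus", lex: FoodLexicon) -> list[TweetFoodProfile]:
    """Score every tweet of a food-filtered corpus.

    Raises
    ------
    ValueError
        If a tweet yields zero matches, which means the corpus was not
        food-filtered against the same lexicon (precondition breach).
    """
    profiles = []
    for tweet in corpus:
        matches = match_foods(tweet.text, lex)
        if not matches:
            raise ValueError(
                f"tweet {tweet.id!r} has no food match; corpus is not food-filtered"
            )
        profiles.append(score_tweet(tweet, matches))
    return profiles
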