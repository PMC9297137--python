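"""Summed-polarity sentiment scoring and the six sentiment-by-category flags.

Every token found in the polarity lexicon contributes +1 or -1 to the
tweet's sentiment score (absent words contribute 0); the sign of the sum
gives the label.  A tweet then raises up to one flag per food category it
mentions — e.g. ``healthy_pos`` for a positive-label tweet with at least
one healthy-food match.  Neutral tweets raise no flags but still count in
every denominator downstream.  There is no negation handling: the method
is a plain lexicon sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._tokenize import tokenize
from .matching import TweetFoodProfile

#: The six sentiment-by-category flags, in reporting order.
FLAG_NAMES: tuple[str, ...] = (
    "healthy_pos",
    "healthy_neg",
    "unhealthy_pos",
    "unhealthy_neg",
    "fastfood_pos",
    "fastfood_neg",
)


@dataclass(frozen=True)
class SentimentResult:
    score: int
    label: str  # positive | negative | neutral
    flags: Mapping[str, bool]


def sentiment_score(text: str, lex: Mapping[str, int]) -> int:
    """Sum of word polarities over the tweet's tokens (repeats count)."""
    return sum(lex.get(token, 0) for token in tokenize(text))


def sentiment_label(score: int) -> str:
    if score > 0:
        return "positive"
    if score < 0:
        return "negative"
    return "neutral"


def flag_tweet(
    profile: TweetFoodProfile, label: str, score: int | None = None
) -> SentimentResult:
    """Derive the six flags from category counts and the sentiment label.

    For each category with at least one match, the flag matching the
    label's polarity is set; a neutral label sets none.
    """
    counts = {
        "healthy": profile.n_healthy,
        "unhealthy": profile.n_unhealthy,
        "fastfood": profile.n_fastfood,
    }
    suffix = {"positive": "pos", "negative": "neg"}.get(label)
    flags = {name: False for name in FLAG_NAMES}
    if suffix is not None:
        for category, count in counts.items():
            if count >= 1:
                flags[f"{category}_{suffix}"] = True
    if score is None:
        score = {"positive": 1, "negative": -1, "neutral": 0}[label]
    return SentimentResult(score=score, label=label, flags=flags)


def analyze_tweet(
    text: str, profile: TweetFoodProfile, lex: Mapping[str, int]
) -> SentimentResult:
    """Score, label and flag one tweet in a single call."""
    score = sentiment_score(text, lex)
    return flag_tweet(profile, sentiment_label(score), score=score)
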