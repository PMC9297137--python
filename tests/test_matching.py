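"""Greedy longest-first keyword matching against a brute-force oracle,
plus per-tweet nutrient/category scoring."""

import numpy as np
import pytest

from foodtract._tokenize import tokenize
from foodtract.ingest import Tweet, TweetCorpus
from foodtract.lexicon import FoodEntry, FoodLexicon
from foodtract.matching import match_foods, profile_corpus, score_tweet

# ---------------------------------------------------------------------------
# Independent oracle: repeatedly pick the longest, leftmost placement over
# not-yet-consumed tokens (exact beats plural at the same spot), consume it,
# and rescan.  Deliberately O(n^2)-ish and structured nothing like the
# single-pass implementation.


def oracle_match(tokens, entries, plural=True):
    consumed: set[int] = set()
    chosen = []
    while True:
        candidates = []
        for entry in entries:
            words = entry.keyword.split()
            k = len(words)
            for start in range(len(tokens) - k + 1):
                if any(i in consumed for i in range(start, start + k)):
                    continue
                seg = tokens[start : start + k]
                exact = seg == words
                plural_hit = (
                    plural
                    and k == 1
                    and len(seg[0]) > 2
                    and seg[0].endswith("s")
                    and not seg[0].endswith("ss")
                    and seg[0][:-1] == words[0]
                )
                if exact or plural_hit:
                    candidates.append((-k, start, 0 if exact else 1, entry.keyword, entry))
        if not candidates:
            break
        candidates.sort()
        negk, start, _, _, entry = candidates[0]
        consumed.update(range(start, start - negk))
        chosen.append((start, entry.keyword))
    return [kw for _, kw in sorted(chosen)]


def random_case(rng):
    vocab = ["ant", "bee", "cat", "dog", "elk", "fox", "gnu", "hen"]
    n_keywords = int(rng.integers(1, 7))
    keywords = set()
    while len(keywords) < n_keywords:
        k = int(rng.integers(1, 4))
        keywords.add(" ".join(rng.choice(vocab, size=k)))
    entries = [FoodEntry(kw, "healthy", {}) for kw in sorted(keywords)]
    n_tokens = int(rng.integers(0, 13))
    tokens = [str(w) for w in rng.choice(vocab, size=n_tokens)]
    # sprinkle plural forms to exercise the trailing-s rule
    tokens = [t + "s" if rng.random() < 0.15 else t for t in tokens]
    return tokens, entries


def test_matcher_equals_bruteforce_oracle_on_random_cases(rng):
    lexicons = {}
    for _ in range(800):
        tokens, entries = random_case(rng)
        key = tuple(e.keyword for e in entries)
        lex = lexicons.setdefault(key, FoodLexicon(entries))
        got = [m.keyword for m in match_foods(" ".join(tokens), lex)]
        assert got == oracle_match(tokens, entries)


# ---------------------------------------------------------------------------
# Worked examples


def test_multiword_keyword_shadows_its_component(tiny_lexicon):
    matches = match_foods("Craving Burger King tonight", tiny_lexicon)
    assert [m.keyword for m in matches] == ["burger king"]


def test_remaining_text_matches_shorter_keyword(tiny_lexicon):
    matches = match_foods("Burger King burger", tiny_lexicon)
    assert [m.keyword for m in matches] == ["burger king", "burger"]
    assert matches[0].category == "fastfood"
    assert matches[1].category == "unhealthy"


def test_repeated_keyword_counts_every_occurrence(tiny_lexicon):
    assert [m.keyword for m in match_foods("burger burger", tiny_lexicon)] == [
        "burger",
        "burger",
    ]


def test_no_match_returns_empty(tiny_lexicon):
    assert match_foods("soup or salad", tiny_lexicon) == []
    assert match_foods("", tiny_lexicon) == []


def test_three_word_keyword_beats_inner_word(tiny_lexicon):
    matches = match_foods("red velvet cake slice", tiny_lexicon)
    assert [m.keyword for m in matches] == ["red velvet cake"]


def test_plural_tolerance_single_words(tiny_lexicon):
    assert [m.keyword for m in match_foods("two burgers", tiny_lexicon)] == ["burger"]
    assert match_foods("two burgers", tiny_lexicon, plural_tolerance=False) == []


def test_matching_invariant_to_case_and_whitespace(tiny_lexicon):
    a = match_foods("BURGER   king \t and APPLE", tiny_lexicon)
    b = match_foods("burger king and apple", tiny_lexicon)
    assert [m.keyword for m in a] == [m.keyword for m in b]


def test_spans_are_disjoint_and_in_text_order(rng):
    for _ in range(200):
        tokens, entries = random_case(rng)
        matches = match_foods(" ".join(tokens), FoodLexicon(entries))
        seen: set[int] = set()
        starts = []
        for m in matches:
            assert not (set(m.span) & seen)
            seen.update(m.span)
            starts.append(m.span[0])
        assert starts == sorted(starts)


# ---------------------------------------------------------------------------
# Scoring


def _tweet(text="x", tid="t1"):
    return Tweet(tid, text=text)


def test_score_averages_nutrients(tiny_lexicon):
    matches = match_foods("apple cake", tiny_lexicon)
    profile = score_tweet(_tweet(), matches)
    # cholesterol: apple 0, cake 55
    assert profile.mean_nutrients["cholesterol"] == pytest.approx(27.5)
    assert profile.n_healthy == 1 and profile.n_unhealthy == 1


def test_single_match_mean_is_identity(tiny_lexicon):
    matches = match_foods("apple", tiny_lexicon)
    profile = score_tweet(_tweet(), matches)
    assert dict(profile.mean_nutrients) == dict(tiny_lexicon["apple"].nutrients)


def test_available_case_mean_ignores_missing(tiny_lexicon):
    # kale has potassium 491, burger has none
    matches = match_foods("kale burger", tiny_lexicon)
    profile = score_tweet(_tweet(), matches)
    assert profile.mean_nutrients["potassium"] == pytest.approx(491)
    # cholesterol only from burger
    assert profile.mean_nutrients["cholesterol"] == pytest.approx(55)


def test_category_restricted_calorie_means(tiny_lexicon):
    profile = score_tweet(_tweet(), match_foods("apple cake burger king", tiny_lexicon))
    assert profile.mean_calories_healthy == pytest.approx(52)
    assert profile.mean_calories_unhealthy == pytest.approx(350)
    assert profile.n_fastfood == 1


def test_zero_matches_gives_empty_profile(tiny_lexicon):
    profile = score_tweet(_tweet(), [])
    assert profile.n_healthy == profile.n_unhealthy == profile.n_fastfood == 0
    assert profile.mean_nutrients == {}
    assert profile.mean_calories_healthy is None


def test_counts_sum_to_match_count_and_means_bounded(rng, tiny_lexicon):
    texts = ["apple cake burger", "kale kale", "burger king apple cake red velvet cake"]
    for text in texts:
        matches = match_foods(text, tiny_lexicon)
        profile = score_tweet(_tweet(text), matches)
        assert profile.n_healthy + profile.n_unhealthy + profile.n_fastfood == len(matches)
        for name, value in profile.mean_nutrients.items():
            contributing = [m.nutrients[name] for m in matches if name in m.nutrients]
            assert min(contributing) <= value <= max(contributing)


def test_profile_corpus_requires_food_filtered_input(tiny_lexicon):
    good = TweetCorpus((Tweet("a", text="apple"), Tweet("b", text="cake")))
    assert len(profile_corpus(good, tiny_lexicon)) == 2
    bad = TweetCorpus((Tweet("a", text="apple"), Tweet("b", text="rainy day")))
    with pytest.raises(ValueError, match="food"):
        profile_corpus(bad, tiny_lexicon)
    assert profile_corpus(TweetCorpus(()), tiny_lexicon) == []


def test_tokenizer_strips_urls_mentions_and_hashtags():
    tokens = tokenize("Lunch @joe https://x.co/a #BurgerKing!! fries")
    assert tokens == ["lunch", "burgerking", "fries"]
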