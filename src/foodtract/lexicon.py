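"""Food and sentiment lexicons.

The food lexicon maps lowercase keyword phrases (single foods, dishes,
fast-food restaurant names) to a diet category — ``healthy``, ``unhealthy``
or ``fastfood`` — and a per-100 g nutrient profile.  Restaurant-name
entries typically carry no nutrient profile at all; individual nutrient
fields may be missing for any entry.

The sentiment lexicon is a plain word -> polarity (+1/-1) mapping used for
summed-polarity sentiment scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._tokenize import normalize_phrase

#: Per-100 g nutrient fields carried by every food entry, with the fatty
#: acids split into saturated / trans / unsaturated fractions.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "calories",
    "calcium",
    "carbohydrates",
    "cholesterol",
    "energy",
    "fat",
    "fiber",
    "iron",
    "potassium",
    "protein",
    "saturated_fatty_acids",
    "sodium",
    "sugar",
    "trans_fatty_acids",
    "unsaturated_fatty_acids",
    "vitamin_a",
    "vitamin_c",
)

CATEGORIES: tuple[str, ...] = ("healthy", "unhealthy", "fastfood")

FOOD_LEXICON_COLUMNS: tuple[str, ...] = ("keyword", "category") + NUTRIENT_FIELDS


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon inputs."""


@dataclass(frozen=True)
class FoodEntry:
    """One food keyword with its category and per-100 g nutrient vector.

    ``nutrients`` maps nutrient field name -> non-negative value; missing
    nutrients are simply absent from the mapping.
    """

    keyword: str
    category: str
    nutrients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.keyword or self.keyword != normalize_phrase(self.keyword):
            raise LexiconError(f"keyword not normalized: {self.keyword!r}")
        if self.category not in CATEGORIES:
            raise LexiconError(
                f"unknown category {self.category!r} for keyword {self.keyword!r}"
            )
        for name, value in self.nutrients.items():
            if name not in NUTRIENT_FIELDS:
                raise LexiconError(f"unknown nutrient field {name!r}")
            if not value >= 0:
                raise LexiconError(
                    f"negative nutrient {name}={value} for keyword {self.keyword!r}"
                )

    @property
    def n_words(self) -> int:
        return len(self.keyword.split())


class FoodLexicon:
    """Keyword -> :class:`FoodEntry` store with a by-word-count index.

    The index groups entries by the number of words in the keyword, in
    strictly decreasing word count, which is the order the greedy
    longest-first matcher consumes them in.
    """

    def __init__(self, entries: Iterable[FoodEntry]):
        self._entries: dict[str, FoodEntry] = {}
        for entry in entries:
            if entry.keyword in self._entries:
                raise LexiconError(f"duplicate keyword: {entry.keyword!r}")
            self._entries[entry.keyword] = entry
        index: dict[int, dict[tuple[str, ...], FoodEntry]] = {}
        for entry in self._entries.values():
            index.setdefault(entry.n_words, {})[tuple(entry.keyword.split())] = entry
        #: word count -> {token tuple -> entry}, keys in decreasing order
        self.word_count_index: dict[int, dict[tuple[str, ...], FoodEntry]] = {
            k: index[k] for k in sorted(index, reverse=True)
        }

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[FoodEntry]:
        return iter(self._entries.values())

    def __contains__(self, keyword: str) -> bool:
        return keyword in self._entries

    def __getitem__(self, keyword: str) -> FoodEntry:
        return self._entries[keyword]

    @property
    def max_words(self) -> int:
        return max(self.word_count_index, default=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self._entries.values():
            row: dict[str, object] = {"keyword": entry.keyword, "category": entry.category}
            for name in NUTRIENT_FIELDS:
                row[name] = entry.nutrients.get(name, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows, columns=list(FOOD_LEXICON_COLUMNS))

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ValidationReport:
    """Pure summary of a loaded food lexicon."""

    n_entries: int
    category_counts: Mapping[str, int]
    nutrient_missingness: Mapping[str, float]


def load_food_lexicon(path: str | Path) -> FoodLexicon:
    """Load and validate a food lexicon CSV.

    The CSV carries ``keyword``, ``category`` and the 17 nutrient columns;
    empty nutrient cells denote missing values.  Keywords are lowercased and
    internal whitespace is collapsed before uniqueness is enforced, so the
    on-disk file may use mixed case.

    Raises
    ------
    LexiconError
        On a missing column, duplicate keyword (the offending keyword is
        named), unknown category, or negative nutrient value.
    """
    return food_lexicon_from_frame(pd.read_csv(path, dtype={"keyword": str, "category": str}))


def food_lexicon_from_frame(df: pd.DataFrame) -> FoodLexicon:
    """Validate and build a :class:`FoodLexicon` from an in-memory table."""
    missing_cols = [c for c in FOOD_LEXICON_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LexiconError(f"food lexicon is missing columns: {missing_cols}")
    entries = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        if pd.isna(row["keyword"]) or pd.isna(row["category"]):
            raise LexiconError(f"unparseable lexicon row: {row.to_dict()!r}")
        keyword = normalize_phrase(str(row["keyword"]))
        if keyword in seen:
            raise LexiconError(f"duplicate keyword: {keyword!r}")
        seen.add(keyword)
        nutrients = {
            name: float(row[name]) for name in NUTRIENT_FIELDS if pd.notna(row[name])
        }
        entries.append(
            FoodEntry(keyword=keyword, category=str(row["category"]).strip(), nutrients=nutrients)
        )
    return FoodLexicon(entries)


def load_sentiment_lexicon(path: str | Path) -> dict[str, int]:
    """Load a word-polarity lexicon CSV (columns ``word``, ``polarity``).

    ``positive`` maps to +1 and ``negative`` to -1; any other polarity
    string is an error, as is the same word listed with both polarities.
    """
    return sentiment_lexicon_from_frame(pd.read_csv(path, dtype=str))


def sentiment_lexicon_from_frame(df: pd.DataFrame) -> dict[str, int]:
    """Validate and build a word -> +/-1 polarity mapping from a table."""
    for col in ("word", "polarity"):
        if col not in df.columns:
            raise LexiconError(f"sentiment lexicon is missing column {col!r}")
    mapping: dict[str, int] = {}
    values = {"positive": 1, "negative": -1}
    for _, row in df.iterrows():
        word = str(row["word"]).strip().lower()
        polarity = str(row["polarity"]).strip().lower()
        if polarity not in values:
            raise LexiconError(f"unknown polarity {polarity!r} for word {word!r}")
        value = values[polarity]
        if word in mapping and mapping[word] != value:
            raise LexiconError(f"conflicting polarities for word {word!r}")
        mapping[word] = value
    return mapping


def validate_lexicon(lex: FoodLexicon) -> ValidationReport:
    """Summarise entry counts per category and nutrient missingness."""
    counts = {c: 0 for c in CATEGORIES}
    present = {name: 0 for name in NUTRIENT_FIELDS}
    for entry in lex:
        counts[entry.category] += 1
        for name in entry.nutrients:
            present[name] += 1
    n = len(lex)
    missingness = {
        name: (1.0 - present[name] / n) if n else 0.0 for name in NUTRIENT_FIELDS
    }
    return ValidationReport(
        n_entries=n, category_counts=counts, nutrient_missingness=missingness
    )
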