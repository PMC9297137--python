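"""Tweet ingestion and the three corpus filters.

A corpus is reduced in three steps before any feature is derived from it:
posts must carry GPS coordinates, promotional posts (job ads and the like,
recognised by hashtags such as ``#hiring``) are dropped, and only posts
matching at least one food keyword survive.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from .lexicon import FoodLexicon
from .matching import match_foods

logger = logging.getLogger(__name__)

#: Hashtags identifying promotional / job-posting content.
DEFAULT_BLOCKLIST: frozenset[str] = frozenset({"#jobs", "#hiring", "#ad", "#job"})


class IngestError(ValueError):
    """Raised for unreadable or empty tweet inputs."""


@dataclass(frozen=True)
class Tweet:
    """One short geotagged post. Coordinates are both present or both missing."""

    id: str
    user_id: str = ""
    timestamp: str = ""
    text: str = ""
    latitude: float | None = None
    longitude: float | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class TweetCorpus:
    """Ordered tweet collection with an append-only filter history."""

    tweets: tuple[Tweet, ...]
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self.tweets)

    def with_step(self, tweets: list[Tweet], note: str) -> "TweetCorpus":
        return TweetCorpus(tuple(tweets), self.provenance + (note,))


def _coerce_record(rec: dict) -> Tweet | None:
    """Build a Tweet from a raw record, or None if it is unusable."""
    rid = rec.get("id")
    text = rec.get("text")
    if rid is None or text is None or str(text) == "" or str(rid) == "":
        return None
    lat = rec.get("lat", rec.get("latitude"))
    lon = rec.get("lon", rec.get("longitude"))
    try:
        lat = None if lat in (None, "") else float(lat)
        lon = None if lon in (None, "") else float(lon)
    except (TypeError, ValueError):
        lat = lon = None
    if (lat is None) != (lon is None):  # half a coordinate pair is no pair
        lat = lon = None
    return Tweet(
        id=str(rid),
        user_id=str(rec.get("user_id", "") or ""),
        timestamp=str(rec.get("timestamp", "") or ""),
        text=str(text),
        latitude=lat,
        longitude=lon,
    )


def read_tweets(path: str | Path, format: str | None = None) -> TweetCorpus:
    """Read a tweet table from JSONL or CSV into a corpus.

    Malformed records (missing id or text, unparseable JSON lines) are
    counted and logged, not fatal; duplicate ids keep the first occurrence.

    Raises
    ------
    IngestError
        If the file cannot be read or contains zero parseable records.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise IngestError(f"unknown tweet format {format!r}")
    try:
        raw_text = path.read_text()
    except OSError as exc:
        raise IngestError(f"cannot read tweet file {path}: {exc}") from exc

    records: list[dict] = []
    n_bad = 0
    if format == "jsonl":
        for line in raw_text.splitlines():
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError:
                n_bad += 1
                continue
            records.append(rec if isinstance(rec, dict) else {})
    else:
        reader = csv.DictReader(raw_text.splitlines())
        records.extend(dict(row) for row in reader)

    tweets: list[Tweet] = []
    seen: set[str] = set()
    for rec in records:
        tweet = _coerce_record(rec)
        if tweet is None or tweet.id in seen:
            n_bad += 1
            continue
        seen.add(tweet.id)
        tweets.append(tweet)
    if not tweets:
        raise IngestError(f"no parseable tweet records in {path}")
    if n_bad:
        logger.info("read_tweets: skipped %d malformed/duplicate records", n_bad)
    return TweetCorpus(
        tuple(tweets), (f"read {len(tweets)} tweets from {path} ({n_bad} skipped)",)
    )


def filter_geolocated(corpus: TweetCorpus) -> TweetCorpus:
    """Keep tweets with both coordinates present and in valid WGS84 range."""
    kept = [
        t
        for t in corpus
        if t.has_coordinates
        and -90.0 <= t.latitude <= 90.0
        and -180.0 <= t.longitude <= 180.0
    ]
    return corpus.with_step(kept, f"filter_geolocated: kept {len(kept)}/{len(corpus)}")


def filter_promotional(
    corpus: TweetCorpus, blocklist: frozenset[str] | set[str] = DEFAULT_BLOCKLIST
) -> TweetCorpus:
    """Drop tweets containing any blocklisted hashtag/keyword token.

    Matching is token-based on the whitespace-split lowercased text, so
    ``#ad`` removes a tweet containing the token ``#ad`` but not one
    containing ``#advice`` or the bare word ``ad``.
    """
    if not blocklist:
        raise ValueError("blocklist must be non-empty")
    block = {b.lower() for b in blocklist}
    kept = [
        t for t in corpus if not (set(t.text.lower().split()) & block)
    ]
    return corpus.with_step(kept, f"filter_promotional: kept {len(kept)}/{len(corpus)}")


def filter_food_related(corpus: TweetCorpus, lex: FoodLexicon) -> TweetCorpus:
    """Keep tweets whose text matches at least one food keyword."""
    kept = [t for t in corpus if match_foods(t.text, lex)]
    return corpus.with_step(kept, f"filter_food_related: kept {len(kept)}/{len(corpus)}")
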