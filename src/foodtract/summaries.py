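"""Worked-example share arithmetic on corpus summary counts.

Corpus-level descriptives of a geotagged collection are simple ratios of
counts: city shares of tweets and users, the share of manually annotated
posts judged truly food-related, the food-desert prevalence among labeled
tracts.  These helpers compute those ratios from count tables so the
arithmetic is reproducible without the raw corpus; per-city summary
counts for a 25-city, March-December 2020 collection ship as package
data.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable

import pandas as pd


def proportion_pct(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def load_city_counts() -> pd.DataFrame:
    """Published per-city tweet and user counts (25 cities)."""
    with resources.files("foodtract").joinpath("data/city_tweet_counts.csv").open() as fh:
        return pd.read_csv(fh)


def city_share_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add percentage-share columns for tweets and users per city."""
    out = counts.copy()
    out["pct_tweets"] = 100.0 * out["n_tweets"] / out["n_tweets"].sum()
    out["pct_users"] = 100.0 * out["n_users"] / out["n_users"].sum()
    return out


def annotation_share_pct(labels: Iterable[bool]) -> float:
    """Share (%) of annotated posts judged truly food-related."""
    labels = list(labels)
    if not labels:
        raise ValueError("no annotation labels")
    return proportion_pct(sum(bool(x) for x in labels), len(labels))


def desert_prevalence_pct(is_desert: Iterable[bool]) -> float:
    """Share (%) of tracts labeled food deserts."""
    flags = list(is_desert)
    if not flags:
        raise ValueError("no tracts")
    return proportion_pct(sum(bool(x) for x in flags), len(flags))
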