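"""Tract-level feature aggregation, SES merge and USDA food-desert labeling.

Per-tweet food profiles and sentiment results are rolled up to one row per
census tract: six sentiment-by-category percentages (denominator = all the
tract's food-related tweets, neutral tweets included), three mean mention
counts, 17 mean per-item nutrient values and category-restricted calorie
means — 28 features in all.  The tract rows are then inner-joined with the
12 demographic/SES covariates, and each tract is labeled a food desert iff
it is both low-income and low-access under the USDA Food Access Research
Atlas criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import TweetFoodProfile
from .sentiment import FLAG_NAMES, SentimentResult

logger = logging.getLogger(__name__)

#: Box-3-ordered nutrient feature names (note fiber/iron/potassium precede
#: fat/protein in the reporting order).
_NUTRIENT_FEATURE_ORDER: tuple[str, ...] = (
    "calories",
    "calcium",
    "carbohydrates",
    "cholesterol",
    "energy",
    "fiber",
    "iron",
    "potassium",
    "fat",
    "protein",
    "saturated_fatty_acids",
    "sodium",
    "sugar",
    "trans_fatty_acids",
    "unsaturated_fatty_acids",
    "vitamin_a",
    "vitamin_c",
)

SENTIMENT_FEATURES: tuple[str, ...] = tuple(f"pct_{name}" for name in FLAG_NAMES)

MENTION_FEATURES: tuple[str, ...] = (
    "mean_healthy_mentions",
    "mean_unhealthy_mentions",
    "mean_fastfood_mentions",
)

NUTRITION_FEATURES: tuple[str, ...] = (
    MENTION_FEATURES
    + tuple(f"mean_{n}" for n in _NUTRIENT_FEATURE_ORDER)
    + ("mean_calories_healthy", "mean_calories_unhealthy")
)

#: The 28 tract-level features derived from tweets, in reporting order.
TRACT_FEATURES: tuple[str, ...] = SENTIMENT_FEATURES + NUTRITION_FEATURES

#: The 12 demographic / socioeconomic covariates.
SES_FEATURES: tuple[str, ...] = (
    "pct_white_nonhispanic",
    "pct_black",
    "pct_other_race",
    "pct_asian",
    "pct_aian",
    "pct_owner_occupied",
    "pct_below_poverty",
    "n_housing_units",
    "n_households",
    "median_family_income",
    "median_age",
    "population",
)

#: Additional inputs consumed only by the USDA labeling step.
LABEL_INPUTS: tuple[str, ...] = (
    "state_median_family_income",
    "metro_median_family_income",
    "n_low_access",
    "pct_low_access",
)


@dataclass(frozen=True)
class FoodDesertLabel:
    """USDA-style label: food desert = low-income AND low-access."""

    tract_id: str
    low_income: bool
    low_access: bool
    is_food_desert: bool
    criteria_met: frozenset[str]


def label_food_desert(ses: Mapping[str, object]) -> FoodDesertLabel:
    """Apply the USDA low-income / low-access criteria to one tract.

    Low income: poverty rate >= 20%, or median family income at most 80%
    of the state median, or (when a metro median is supplied) at most 80%
    of the metro median.  Low access: >= 500 residents, or >= 33% of
    residents, far from a supermarket.  All boundaries are inclusive.
    """
    poverty = float(ses["pct_below_poverty"])
    income = float(ses["median_family_income"])
    state_income = float(ses["state_median_family_income"])
    metro_income = ses.get("metro_median_family_income")
    n_low_access = float(ses["n_low_access"])
    pct_low_access = float(ses["pct_low_access"])
    if n_low_access < 0 or income < 0:
        raise ValueError(f"negative labeling input for tract {ses.get('tract_id')!r}")

    criteria: set[str] = set()
    if poverty >= 20.0:
        criteria.add("poverty20")
    if income <= 0.80 * state_income:
        criteria.add("income80_state")
    if metro_income is not None and not pd.isna(metro_income):
        if income <= 0.80 * float(metro_income):
            criteria.add("income80_metro")
    if n_low_access >= 500:
        criteria.add("access500")
    if pct_low_access >= 33.0:
        criteria.add("access33pct")

    low_income = bool(criteria & {"poverty20", "income80_state", "income80_metro"})
    low_access = bool(criteria & {"access500", "access33pct"})
    return FoodDesertLabel(
        tract_id=str(ses.get("tract_id", "")),
        low_income=low_income,
        low_access=low_access,
        is_food_desert=low_income and low_access,
        criteria_met=frozenset(criteria),
    )


def aggregate_tract_features(
    profiles: Sequence[TweetFoodProfile],
    sentiments: Sequence[SentimentResult],
    mapping: Mapping[str, str],
    known_tracts: set[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-tweet profiles to one feature row per tract.

    ``profiles`` and ``sentiments`` are aligned per tweet; ``mapping``
    assigns tweet ids to tract ids (tweets absent from the mapping are
    dropped as unmapped).  Returns a DataFrame with ``tract_id``,
    ``n_tweets`` and the 28 features; nutrient means are available-case
    (NaN only when no tweet in the tract contributes).
    """
    if len(profiles) != len(sentiments):
        raise ValueError("profiles and sentiments must align one-to-one")
    rows = []
    for profile, senti in zip(profiles, sentiments):
        tract = mapping.get(profile.tweet_id)
        if tract is None:
            continue
        if known_tracts is not None and tract not in known_tracts:
            raise ValueError(f"tweet {profile.tweet_id!r} mapped to unknown tract {tract!r}")
        row: dict[str, object] = {"tract_id": tract}
        for flag in FLAG_NAMES:
            row[f"pct_{flag}"] = float(senti.flags[flag])
        row["mean_healthy_mentions"] = profile.n_healthy
        row["mean_unhealthy_mentions"] = profile.n_unhealthy
        row["mean_fastfood_mentions"] = profile.n_fastfood
        for name in _NUTRIENT_FEATURE_ORDER:
            row[f"mean_{name}"] = profile.mean_nutrients.get(name, np.nan)
        row["mean_calories_healthy"] = (
            np.nan if profile.mean_calories_healthy is None else profile.mean_calories_healthy
        )
        row["mean_calories_unhealthy"] = (
            np.nan
            if profile.mean_calories_unhealthy is None
            else profile.mean_calories_unhealthy
        )
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["tract_id", "n_tweets", *TRACT_FEATURES])
    df = pd.DataFrame(rows)
    grouped = df.groupby("tract_id", sort=True)
    out = grouped.size().rename("n_tweets").to_frame()
    means = grouped[list(TRACT_FEATURES)].mean()  # NaN-skipping = available-case
    for col in SENTIMENT_FEATURES:
        means[col] = means[col] * 100.0
    out = out.join(means).reset_index()
    return out[["tract_id", "n_tweets", *TRACT_FEATURES]]


def merge_ses(features: pd.DataFrame, ses: pd.DataFrame) -> pd.DataFrame:
    """Inner-join tract feature rows with the SES table on ``tract_id``.

    Tracts lacking SES are dropped with a logged count; a duplicated
    tract id on either side is an error.
    """
    for name, df in (("features", features), ("ses", ses)):
        if df["tract_id"].duplicated().any():
            dupes = df.loc[df["tract_id"].duplicated(), "tract_id"].tolist()
            raise ValueError(f"duplicate tract_id in {name} table: {dupes[:5]}")
    merged = features.merge(ses, on="tract_id", how="inner", validate="one_to_one")
    dropped = len(features) - len(merged)
    if dropped:
        logger.info("merge_ses: dropped %d feature rows lacking SES", dropped)
    return merged


def label_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append USDA label columns to a merged analysis table."""
    labels = [label_food_desert(row) for row in table.to_dict("records")]
    out = table.copy()
    out["low_income"] = [lab.low_income for lab in labels]
    out["low_access"] = [lab.low_access for lab in labels]
    out["is_food_desert"] = [lab.is_food_desert for lab in labels]
    return out


def build_analysis_table(
    profiles: Sequence[TweetFoodProfile],
    sentiments: Sequence[SentimentResult],
    mapping: Mapping[str, str],
    ses: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate, merge SES and label in one step.

    The result is the contract between the upstream text pipeline and the
    statistics modules: one row per tract with >= 1 mapped food-related
    tweet, 28 feature columns, 12 SES columns, labeling inputs and the
    label columns.
    """
    features = aggregate_tract_features(profiles, sentiments, mapping)
    merged = merge_ses(features, ses)
    return label_table(merged)


def save_analysis_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_analysis_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tract_id": str})
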