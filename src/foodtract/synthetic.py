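"""Synthetic study-data generator.

Emulates the five pipeline inputs without any download: unit-square census
tracts on a grid (GeoJSON), an SES/demographics table whose values are
drawn near published tract-level means and in which an exact configured
count of tracts satisfies the USDA low-income/low-access criteria, a
curated food lexicon and polarity lexicon, and a geotagged tweet corpus.

Food-desert effects are implanted at the *sampling-probability* level, not
by editing aggregated features: tweets from desert tracts draw unhealthy
keywords more often, draw high-cholesterol unhealthy items and
low-potassium healthy items preferentially (exponential tilt), and are
more likely to be positive when they mention healthy foods or fast-food
restaurants.  The downstream pipeline therefore has to transmit the signal
through matching, sentiment, mapping and aggregation before the
association screen can recover it.  Default effect magnitudes were chosen
once, by an a priori power calculation, so each implanted effect is
detectable with high power at 1000 tracts and a median of ~4 tweets per
tract; setting every delta/tilt to zero yields null data for calibration.

Promotional posts (#hiring etc.) and posts without coordinates are
injected at configurable rates purely to exercise the ingest filters.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .features import label_food_desert
from .ingest import Tweet, TweetCorpus
from .lexicon import (
    FOOD_LEXICON_COLUMNS,
    FoodLexicon,
    NUTRIENT_FIELDS,
    food_lexicon_from_frame,
)

#: Table-5-signed direction of each implanted effect (sign of the expected
#: food-desert coefficient in the association screen).
IMPLANTED_SIGNS: dict[str, int] = {
    "pct_healthy_pos": +1,
    "pct_fastfood_pos": +1,
    "mean_unhealthy_mentions": +1,
    "mean_cholesterol": +1,
    "mean_potassium": -1,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Effect deltas are probability shifts applied when a tract is a food
    desert; tilts are exponential-weighting strengths on standardized
    nutrient values when choosing which food keyword a desert-tract tweet
    mentions.  ``food_desert_fraction`` defaults to 7.52%, the observed
    food-desert prevalence among US census tracts with geolocated
    food-related tweets in the emulated collection.
    """

    n_tracts: int = 500
    food_desert_fraction: float = 0.0752
    seed: int = 0
    # tweet volume: count per tract = 1 + NegBin(mean, shape); median ~ 4
    tweets_nb_mean: float = 3.8
    tweets_nb_shape: float = 1.3
    # base sampling probabilities
    p_positive: float = 0.35
    p_negative: float = 0.20
    p_healthy: float = 0.40
    p_unhealthy: float = 0.35
    p_fastfood: float = 0.25
    mention_rate: float = 0.8  # mentions per tweet = 1 + min(Poisson(rate), 2)
    # implanted food-desert effects (all zero -> null data)
    delta_healthy_pos: float = 0.38
    delta_fastfood_pos: float = 0.45
    delta_unhealthy_mentions: float = 0.15
    cholesterol_tilt: float = 1.2
    potassium_tilt: float = 1.2
    # filter-exercise injections
    promo_fraction: float = 0.04
    nongeo_fraction: float = 0.05
    # SES scaffolding
    state_median_family_income: float = 85_000.0
    metro_median_family_income: float = 88_000.0
    metro_presence_prob: float = 0.7
    extra_low_income_fraction: float = 0.18

    def null(self) -> "SyntheticConfig":
        """Copy of this config with every implanted effect switched off."""
        return SyntheticConfig(
            **{
                **asdict(self),
                "delta_healthy_pos": 0.0,
                "delta_fastfood_pos": 0.0,
                "delta_unhealthy_mentions": 0.0,
                "cholesterol_tilt": 0.0,
                "potassium_tilt": 0.0,
            }
        )

    def validate(self) -> None:
        if not 0.0 <= self.food_desert_fraction <= 1.0:
            raise ValueError("food_desert_fraction must be in [0, 1]")
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be positive")


# --------------------------------------------------------------------------
# Curated lexicons.  Anchor nutrients (per 100 g) are hand-set; the
# remaining fields are filled by fixed formulas so every entry carries a
# complete, plausible profile.  Fast-food restaurant names carry no
# nutrients at all.  The list deliberately contains multi-word keywords
# whose component words are themselves keywords ("burger king"/"burger",
# "red velvet cake"/"cake", "double cheeseburger"/"cheeseburger") to
# exercise longest-first matching.

_HEALTHY: dict[str, tuple[float, float, float]] = {
    # keyword: (calories, cholesterol, potassium)
    "apple": (52, 0, 107),
    "banana": (89, 0, 358),
    "avocado": (160, 0, 485),
    "spinach": (23, 0, 558),
    "kale": (49, 0, 491),
    "blueberries": (57, 0, 77),
    "quinoa": (120, 0, 172),
    "oatmeal": (68, 0, 61),
    "broccoli": (34, 0, 316),
    "sweet potato": (86, 0, 337),
    "lentil soup": (52, 0, 220),
    "greek yogurt": (59, 5, 141),
    "grilled chicken salad": (120, 45, 250),
    "brown rice": (111, 0, 43),
    "orange": (47, 0, 181),
}

# Cholesterol and potassium are kept roughly uncorrelated within the
# unhealthy category so the cholesterol tilt does not drag potassium along.
_UNHEALTHY: dict[str, tuple[float, float, float]] = {
    "burger": (250, 55, 200),
    "cheeseburger": (303, 70, 190),
    "double cheeseburger": (282, 85, 160),
    "fries": (312, 0, 579),
    "donut": (452, 19, 60),
    "cupcake": (305, 38, 98),
    "pizza": (266, 17, 172),
    "fried chicken": (246, 87, 150),
    "milkshake": (112, 12, 183),
    "soda": (41, 0, 2),
    "candy bar": (488, 8, 272),
    "bacon": (541, 110, 170),
    "hot dog": (290, 77, 166),
    "nachos": (306, 28, 172),
    "ice cream": (207, 44, 150),
    "red velvet cake": (367, 52, 90),
    "cake": (350, 55, 80),
}

_FASTFOOD: tuple[str, ...] = (
    "burger king",
    "mcdonalds",
    "taco bell",
    "dairy queen",
    "del taco",
    "popeyes",
    "whataburger",
    "chick fil a",
    "jack in the box",
    "wendys",
)

_POSITIVE_WORDS: tuple[str, ...] = (
    "love", "loved", "great", "good", "delicious", "yummy", "tasty", "amazing",
    "awesome", "fresh", "perfect", "happy", "best", "enjoy", "enjoyed",
    "wonderful", "fantastic", "excellent", "favorite", "divine", "heavenly",
    "glad", "satisfying", "crisp", "bright", "lovely", "superb", "incredible",
    "delightful", "joyful",
)

_NEGATIVE_WORDS: tuple[str, ...] = (
    "hate", "hated", "awful", "terrible", "gross", "nasty", "bad", "worst",
    "bland", "stale", "soggy", "disappointing", "disappointed", "disgusting",
    "horrible", "yuck", "sad", "angry", "upset", "burnt", "greasy", "sick",
    "ruined", "waste", "overpriced", "rude", "slow", "dirty", "mediocre",
    "inedible",
)

_FILLER_WORDS: tuple[str, ...] = (
    "today", "tonight", "lunch", "dinner", "breakfast", "grabbed", "ordered",
    "trying", "place", "downtown", "corner", "again", "finally", "really",
    "just", "some", "with", "friends", "after", "work", "before", "noon",
    "weekend", "craving", "stopped", "by", "the", "new", "spot", "over",
)


def _fill_nutrients(calories: float, cholesterol: float, potassium: float) -> dict:
    """Complete a 17-field nutrient vector from three anchors.

    The derived fields are plausible per-100 g magnitudes tied
    deterministically to the anchors; only the anchors carry implanted
    between-category structure.
    """
    fat = round(0.04 * calories + 0.05 * cholesterol, 2)
    return {
        "calories": calories,
        "calcium": round(30 + 0.2 * potassium, 1),
        "carbohydrates": round(0.12 * calories, 1),
        "cholesterol": cholesterol,
        "energy": round(4.184 * calories, 1),
        "fat": fat,
        "fiber": round(max(0.2, 3.0 - 0.005 * calories), 2),
        "iron": round(0.4 + 0.002 * calories, 2),
        "potassium": potassium,
        "protein": round(0.05 * calories + 0.08 * cholesterol, 1),
        "saturated_fatty_acids": round(0.4 * fat, 2),
        "sodium": round(20 + 3.5 * cholesterol, 1),
        "sugar": round(0.06 * calories, 1),
        "trans_fatty_acids": round(0.03 * fat, 2),
        "unsaturated_fatty_acids": round(0.5 * fat, 2),
        "vitamin_a": round(100 + potassium, 0),
        "vitamin_c": round(max(0.0, 20 - 0.04 * calories), 1),
    }


def generate_lexicons(cfg: SyntheticConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the curated food and polarity lexicon tables.

    The lists are fixed (hence trivially deterministic): 42 food entries
    across the three categories and 60 polarity words.  Healthy entries
    have low cholesterol and a wide potassium spread; unhealthy entries
    the reverse — the spreads the keyword-choice tilts act on.
    """
    rows = []
    for keyword, (cal, chol, potas) in _HEALTHY.items():
        rows.append({"keyword": keyword, "category": "healthy", **_fill_nutrients(cal, chol, potas)})
    for keyword, (cal, chol, potas) in _UNHEALTHY.items():
        rows.append({"keyword": keyword, "category": "unhealthy", **_fill_nutrients(cal, chol, potas)})
    for keyword in _FASTFOOD:
        rows.append({"keyword": keyword, "category": "fastfood", **{n: np.nan for n in NUTRIENT_FIELDS}})
    food = pd.DataFrame(rows, columns=list(FOOD_LEXICON_COLUMNS))
    senti = pd.DataFrame(
        [{"word": w, "polarity": "positive"} for w in _POSITIVE_WORDS]
        + [{"word": w, "polarity": "negative"} for w in _NEGATIVE_WORDS],
        columns=["word", "polarity"],
    )
    return food, senti


# --------------------------------------------------------------------------
# Tracts and SES


@dataclass(frozen=True)
class SyntheticTracts:
    geojson: dict
    ses: pd.DataFrame
    bounds: pd.DataFrame  # tract_id, min_lon, min_lat, max_lon, max_lat
    desert_ids: tuple[str, ...]


def generate_tracts(cfg: SyntheticConfig, rng: np.random.Generator) -> SyntheticTracts:
    """Lay out unit-square tracts on a grid and draw their SES records.

    Exactly ``round(n_tracts * food_desert_fraction)`` tracts receive
    SES/access values satisfying the USDA food-desert criteria; every
    other tract receives values violating the conjunction.  An additional
    slice of tracts is low-income but not low-access, so income alone does
    not identify deserts.  The construction is verified through
    :func:`~foodtract.features.label_food_desert` before returning.
    """
    cfg.validate()
    n = cfg.n_tracts
    n_desert = int(round(n * cfg.food_desert_fraction))
    if n_desert > n:
        raise ValueError("infeasible food_desert_fraction")
    cols = math.ceil(math.sqrt(n))
    ids = [f"SYN{i:06d}" for i in range(n)]
    col = np.arange(n) % cols
    row = np.arange(n) // cols

    desert = np.zeros(n, dtype=bool)
    desert[rng.choice(n, size=n_desert, replace=False)] = True
    # extra low-income (but high-access) tracts among the non-deserts
    non_desert_idx = np.flatnonzero(~desert)
    n_extra_li = int(round(len(non_desert_idx) * cfg.extra_low_income_fraction))
    extra_li = np.zeros(n, dtype=bool)
    if n_extra_li:
        extra_li[rng.choice(non_desert_idx, size=n_extra_li, replace=False)] = True
    low_income = desert | extra_li

    state = cfg.state_median_family_income
    metro = np.where(
        rng.random(n) < cfg.metro_presence_prob, cfg.metro_median_family_income, np.nan
    )
    income_cap = 0.80 * np.fmax(state, np.nan_to_num(metro, nan=0.0))

    base_income = np.clip(rng.normal(82_371.4, 42_680.1, n), 15_000, None)
    poverty = np.clip(rng.normal(16.2, 12.1, n), 1.0, 60.0)
    income = base_income.copy()

    # low-income tracts: draw which criterion route applies
    route = rng.random(n)
    li = low_income
    pov_route = li & (route < 0.4)
    inc_route = li & (route >= 0.4) & (route < 0.7)
    both_route = li & (route >= 0.7)
    poverty[pov_route | both_route] = rng.uniform(21.0, 45.0, int((pov_route | both_route).sum()))
    poverty[inc_route] = rng.uniform(8.0, 19.5, int(inc_route.sum()))
    low_inc_draw = rng.uniform(0.45, 0.78, n) * state
    income[inc_route | both_route] = low_inc_draw[inc_route | both_route]
    income[pov_route] = np.fmax(income[pov_route], 0.0)  # free under poverty route
    # non-low-income tracts must violate every income criterion
    hi = ~li
    poverty[hi] = np.clip(poverty[hi], 1.0, 19.0)
    income[hi] = np.fmax(income[hi], 1.02 * income_cap[hi])

    # access: deserts low-access, other low-income tracts not; the rest free
    n_low_access = rng.integers(0, 500, n).astype(float)
    pct_low_access = rng.uniform(0.0, 32.5, n)
    d = desert
    acc_route = rng.random(n)
    d_count = d & (acc_route < 0.4)
    d_pct = d & (acc_route >= 0.4) & (acc_route < 0.8)
    d_both = d & (acc_route >= 0.8)
    n_low_access[d_count | d_both] = rng.integers(500, 3000, int((d_count | d_both).sum()))
    pct_low_access[d_pct | d_both] = rng.uniform(33.0, 80.0, int((d_pct | d_both).sum()))
    free = hi & ~desert
    free_low_access = free & (rng.random(n) < 0.3)
    n_low_access[free_low_access] = rng.integers(500, 2500, int(free_low_access.sum()))

    housing = np.clip(rng.normal(1788.4, 863.5, n), 100, None).round()
    households = (housing * rng.uniform(0.85, 0.98, n)).round()
    ses = pd.DataFrame(
        {
            "tract_id": ids,
            "pct_white_nonhispanic": np.clip(rng.normal(62.7, 23.4, n), 0, 100),
            "pct_black": np.clip(rng.normal(15.6, 21.0, n), 0, 100),
            "pct_other_race": np.clip(rng.normal(8.9, 12.3, n), 0, 100),
            "pct_asian": np.clip(rng.normal(7.4, 9.2, n), 0, 100),
            "pct_aian": np.clip(rng.normal(1.0, 1.9, n), 0, 100),
            "pct_owner_occupied": np.clip(rng.normal(49.3, 24.8, n), 0, 100),
            "pct_below_poverty": poverty,
            "n_housing_units": housing,
            "n_households": households,
            "median_family_income": income.round(0),
            "median_age": np.clip(rng.normal(37.0, 6.8, n), 18, 80).round(1),
            "population": np.clip(rng.normal(4283.1, 2243.6, n), 200, None).round(),
            "state_median_family_income": state,
            "metro_median_family_income": metro,
            "n_low_access": n_low_access,
            "pct_low_access": pct_low_access,
        }
    )

    labels = [label_food_desert(rec) for rec in ses.to_dict("records")]
    realized = np.array([lab.is_food_desert for lab in labels])
    if not np.array_equal(realized, desert):  # pragma: no cover - construction guard
        raise AssertionError("constructed SES does not reproduce the intended labels")

    features = []
    bounds_rows = []
    for i in range(n):
        x0, y0 = float(col[i]), float(row[i])
        ring = [[x0, y0], [x0 + 1, y0], [x0 + 1, y0 + 1], [x0, y0 + 1], [x0, y0]]
        features.append(
            {
                "type": "Feature",
                "properties": {"GEOID": ids[i]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
        bounds_rows.append(
            {"tract_id": ids[i], "min_lon": x0, "min_lat": y0, "max_lon": x0 + 1, "max_lat": y0 + 1}
        )
    geojson = {"type": "FeatureCollection", "features": features}
    return SyntheticTracts(
        geojson=geojson,
        ses=ses,
        bounds=pd.DataFrame(bounds_rows),
        desert_ids=tuple(np.array(ids)[desert]),
    )


# --------------------------------------------------------------------------
# Tweets


def _tilted_choice(
    rng: np.random.Generator, keywords: list[str], weights: np.ndarray | None
) -> str:
    if weights is None:
        return keywords[rng.integers(len(keywords))]
    return keywords[rng.choice(len(keywords), p=weights)]


def _tilt_weights(values: np.ndarray, tilt: float) -> np.ndarray | None:
    """exp(tilt * z) weights over standardized nutrient values."""
    if tilt == 0.0:
        return None
    sd = values.std()
    z = (values - values.mean()) / (sd if sd > 0 else 1.0)
    w = np.exp(tilt * z)
    return w / w.sum()


def generate_tweets(
    cfg: SyntheticConfig,
    tracts: SyntheticTracts,
    food: pd.DataFrame,
    rng: np.random.Generator,
) -> list[dict]:
    """Draw the geotagged tweet corpus, implanting the configured effects.

    Per tract, a 1 + negative-binomial tweet count; per tweet, 1-3 food
    keyword mentions with category probabilities (desert tracts tilted
    toward unhealthy), nutrient-tilted keyword choice within category for
    desert tracts, a sentiment label whose positive probability is raised
    in desert tracts when healthy foods or fast-food restaurants are
    mentioned, and matching polarity words appended to the text.  A
    configurable share of promotional and non-geolocated posts is added.
    """
    if food.empty:
        raise ValueError("empty food lexicon")
    by_cat = {
        cat: list(food.loc[food["category"] == cat, "keyword"])
        for cat in ("healthy", "unhealthy", "fastfood")
    }
    chol = food.set_index("keyword")["cholesterol"]
    potas = food.set_index("keyword")["potassium"]
    unhealthy_weights = _tilt_weights(
        chol.loc[by_cat["unhealthy"]].to_numpy(float), cfg.cholesterol_tilt
    )
    healthy_weights = _tilt_weights(
        potas.loc[by_cat["healthy"]].to_numpy(float), -cfg.potassium_tilt
    )

    desert_set = set(tracts.desert_ids)
    p_nb = cfg.tweets_nb_shape / (cfg.tweets_nb_shape + cfg.tweets_nb_mean)
    bounds = tracts.bounds.set_index("tract_id")
    n_tracts = len(bounds)
    counts = 1 + rng.negative_binomial(cfg.tweets_nb_shape, p_nb, n_tracts)
    total = int(counts.sum())
    n_users = max(1, total // 3)

    records: list[dict] = []
    serial = 0

    def _timestamp() -> str:
        month = int(rng.integers(3, 13))
        day = int(rng.integers(1, 29))
        hour = int(rng.integers(0, 24))
        minute = int(rng.integers(0, 60))
        return f"2020-{month:02d}-{day:02d}T{hour:02d}:{minute:02d}:00Z"

    def _emit(text: str, tract_id: str | None) -> None:
        nonlocal serial
        rec: dict[str, object] = {
            "id": f"tw{serial:07d}",
            "user_id": f"u{int(rng.integers(n_users)):05d}",
            "timestamp": _timestamp(),
            "text": text,
        }
        if tract_id is not None:
            b = bounds.loc[tract_id]
            rec["lat"] = round(float(b.min_lat + 0.02 + 0.96 * rng.random()), 6)
            rec["lon"] = round(float(b.min_lon + 0.02 + 0.96 * rng.random()), 6)
        records.append(rec)
        serial += 1

    def _food_text(is_desert: bool) -> str:
        m = 1 + min(int(rng.poisson(cfg.mention_rate)), 2)
        p = np.array([cfg.p_healthy, cfg.p_unhealthy, cfg.p_fastfood])
        if is_desert and cfg.delta_unhealthy_mentions:
            shift = cfg.delta_unhealthy_mentions
            p = np.array(
                [cfg.p_healthy - shift * cfg.p_healthy / (cfg.p_healthy + cfg.p_fastfood),
                 cfg.p_unhealthy + shift,
                 cfg.p_fastfood - shift * cfg.p_fastfood / (cfg.p_healthy + cfg.p_fastfood)]
            )
        p = np.clip(p, 0.01, None)
        p = p / p.sum()
        units: list[str] = []
        cats: list[str] = []
        for _ in range(m):
            cat = ("healthy", "unhealthy", "fastfood")[int(rng.choice(3, p=p))]
            cats.append(cat)
            if cat == "unhealthy":
                kw = _tilted_choice(rng, by_cat["unhealthy"], unhealthy_weights if is_desert else None)
            elif cat == "healthy":
                kw = _tilted_choice(rng, by_cat["healthy"], healthy_weights if is_desert else None)
            else:
                kw = by_cat["fastfood"][int(rng.integers(len(by_cat["fastfood"])))]
            if rng.random() < 0.15:
                kw = kw.title()
            elif rng.random() < 0.10 and " " not in kw and not kw.endswith("s"):
                kw = kw + "s"
            units.append(kw)
        # sentiment label, shifted in deserts by the categories mentioned
        p_pos = cfg.p_positive
        if is_desert:
            if "healthy" in cats:
                p_pos += cfg.delta_healthy_pos
            if "fastfood" in cats:
                p_pos += cfg.delta_fastfood_pos
        p_pos = min(p_pos, 0.88)
        u = rng.random()
        if u < p_pos:
            k = 1 + int(rng.random() < 0.3)
            units.extend(rng.choice(_POSITIVE_WORDS, size=k, replace=False))
        elif u < p_pos + cfg.p_negative:
            k = 1 + int(rng.random() < 0.3)
            units.extend(rng.choice(_NEGATIVE_WORDS, size=k, replace=False))
        units.extend(rng.choice(_FILLER_WORDS, size=int(rng.integers(2, 6)), replace=False))
        order = rng.permutation(len(units))
        return " ".join(units[i] for i in order)

    tract_ids = list(bounds.index)
    for tract_id, count in zip(tract_ids, counts):
        is_desert = tract_id in desert_set
        for _ in range(int(count)):
            _emit(_food_text(is_desert), tract_id)

    n_promo = int(round(cfg.promo_fraction * total))
    promo_tags = ("#hiring", "#jobs", "#ad")
    for _ in range(n_promo):
        tag = promo_tags[int(rng.integers(len(promo_tags)))]
        kw = by_cat["unhealthy"][int(rng.integers(len(by_cat["unhealthy"])))]
        tract_id = tract_ids[int(rng.integers(n_tracts))]
        _emit(f"now {tag} line cooks {kw} shift apply", tract_id)
    n_nongeo = int(round(cfg.nongeo_fraction * total))
    for _ in range(n_nongeo):
        _emit(_food_text(False), None)

    order = rng.permutation(len(records))
    return [records[i] for i in order]


# --------------------------------------------------------------------------
# Bundled dataset


@dataclass(frozen=True)
class SyntheticDataset:
    """All five generated inputs plus the implanted ground truth."""

    config: SyntheticConfig
    tweets: list[dict]
    tracts_geojson: dict
    ses: pd.DataFrame
    food_lexicon: pd.DataFrame
    sentiment_lexicon: pd.DataFrame
    desert_ids: tuple[str, ...]

    def to_corpus(self) -> TweetCorpus:
        tweets = []
        for rec in self.tweets:
            tweets.append(
                Tweet(
                    id=str(rec["id"]),
                    user_id=str(rec.get("user_id", "")),
                    timestamp=str(rec.get("timestamp", "")),
                    text=str(rec["text"]),
                    latitude=rec.get("lat"),
                    longitude=rec.get("lon"),
                )
            )
        return TweetCorpus(tuple(tweets), ("synthetic corpus",))

    def food_lex(self) -> FoodLexicon:
        return food_lexicon_from_frame(self.food_lexicon)

    def truth(self) -> dict:
        return {
            "config": asdict(self.config),
            "desert_tract_ids": list(self.desert_ids),
            "implanted_signs": dict(IMPLANTED_SIGNS),
        }


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate tracts, SES, lexicons and tweets from one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tracts = generate_tracts(cfg, rng)
    food, senti = generate_lexicons(cfg)
    tweets = generate_tweets(cfg, tracts, food, rng)
    return SyntheticDataset(
        config=cfg,
        tweets=tweets,
        tracts_geojson=tracts.geojson,
        ses=tracts.ses,
        food_lexicon=food,
        sentiment_lexicon=senti,
        desert_ids=tracts.desert_ids,
    )


def simulate(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the five input files plus truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(cfg)
    paths = {
        "tweets": outdir / "tweets.jsonl",
        "tracts": outdir / "tracts.geojson",
        "ses": outdir / "ses.csv",
        "food_lexicon": outdir / "food_lexicon.csv",
        "sentiment_lexicon": outdir / "sentiment_lexicon.csv",
        "truth": outdir / "truth.json",
    }
    with paths["tweets"].open("w") as fh:
        for rec in ds.tweets:
            fh.write(json.dumps(rec) + "\n")
    paths["tracts"].write_text(json.dumps(ds.tracts_geojson))
    ds.ses.to_csv(paths["ses"], index=False)
    ds.food_lexicon.to_csv(paths["food_lexicon"], index=False)
    ds.sentiment_lexicon.to_csv(paths["sentiment_lexicon"], index=False)
    paths["truth"].write_text(json.dumps(ds.truth(), indent=2))
    return paths
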