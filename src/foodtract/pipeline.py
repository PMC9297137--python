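"""End-to-end orchestration: filters -> scoring -> mapping -> analysis table
-> association screen -> classification benchmark.

Thin glue over the stage modules; each stage remains usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .association import ScreenResult, run_association_screen
from .classification import METHODS, SplitConfig, run_benchmark
from .features import build_analysis_table
from .geospatial import TractAssignment, TractGeometry, map_corpus
from .ingest import (
    DEFAULT_BLOCKLIST,
    TweetCorpus,
    filter_food_related,
    filter_geolocated,
    filter_promotional,
)
from .lexicon import FoodLexicon
from .matching import profile_corpus
from .sentiment import analyze_tweet
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset


@dataclass(frozen=True)
class PipelineResult:
    """Filtered corpus, per-tweet scores, tract assignment and the table."""

    corpus: TweetCorpus
    assignment: TractAssignment
    analysis_table: pd.DataFrame

    @property
    def filter_history(self) -> tuple[str, ...]:
        return self.corpus.provenance


def run_pipeline(
    corpus: TweetCorpus,
    tracts: Sequence[TractGeometry],
    ses: pd.DataFrame,
    food_lex: FoodLexicon,
    sentiment_lex: dict[str, int],
    mode: str = "bbox",
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST,
) -> PipelineResult:
    """Run filters, scoring, mapping and aggregation to the analysis table."""
    corpus = filter_geolocated(corpus)
    corpus = filter_promotional(corpus, blocklist)
    corpus = filter_food_related(corpus, food_lex)
    profiles = profile_corpus(corpus, food_lex)
    sentiments = [
        analyze_tweet(tweet.text, profile, sentiment_lex)
        for tweet, profile in zip(corpus, profiles)
    ]
    assignment = map_corpus(corpus, tracts, mode=mode)
    table = build_analysis_table(profiles, sentiments, assignment.mapping, ses)
    return PipelineResult(corpus=corpus, assignment=assignment, analysis_table=table)


def tracts_from_geojson(geojson: dict, id_property: str = "GEOID") -> list[TractGeometry]:
    """In-memory counterpart of :func:`foodtract.geospatial.load_tracts`."""
    from shapely.geometry import shape

    tracts = []
    for feature in geojson["features"]:
        geom = shape(feature["geometry"])
        tracts.append(
            TractGeometry(
                tract_id=str(feature["properties"][id_property]),
                bbox=geom.bounds,
                polygon=geom,
            )
        )
    return tracts


@dataclass(frozen=True)
class StudyResult:
    """The full synthetic-study output: table, screen and benchmark."""

    analysis_table: pd.DataFrame
    screen: ScreenResult
    benchmark: pd.DataFrame


def run_synthetic_study(
    cfg: SyntheticConfig,
    alpha: float = 0.05,
    split: SplitConfig | None = None,
    methods: Sequence[str] = METHODS,
    models: Sequence[int] = (1, 2, 3, 4, 5),
    dataset: SyntheticDataset | None = None,
    run_classification: bool = True,
) -> StudyResult:
    """Generate data (unless given), run the pipeline, screen and benchmark.

    The split seed defaults to the generator seed, so one seed fixes the
    entire chain.
    """
    from .lexicon import sentiment_lexicon_from_frame

    ds = dataset if dataset is not None else generate_dataset(cfg)
    result = run_pipeline(
        ds.to_corpus(),
        tracts_from_geojson(ds.tracts_geojson),
        ds.ses,
        ds.food_lex(),
        sentiment_lexicon_from_frame(ds.sentiment_lexicon),
    )
    screen = run_association_screen(result.analysis_table, alpha=alpha)
    if run_classification:
        split = split if split is not None else SplitConfig(seed=cfg.seed)
        benchmark = run_benchmark(
            result.analysis_table, split, screen.significant, methods=methods, models=models
        )
    else:
        benchmark = pd.DataFrame()
    return StudyResult(
        analysis_table=result.analysis_table, screen=screen, benchmark=benchmark
    )
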