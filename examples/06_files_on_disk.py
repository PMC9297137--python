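"""Round-trip the pipeline through its on-disk formats.

Writes the five synthetic input files (tweets JSONL, tracts GeoJSON, SES
CSV, two lexicon CSVs), then re-reads everything through the file loaders
and runs the pipeline — the path a user with real data files would take.
"""

import tempfile
from pathlib import Path

from foodtract import (
    SyntheticConfig,
    load_food_lexicon,
    load_sentiment_lexicon,
    load_tracts,
    read_tweets,
    run_pipeline,
    simulate,
)
import pandas as pd

with tempfile.TemporaryDirectory() as tmp:
    paths = simulate(SyntheticConfig(n_tracts=100, seed=3), tmp)
    for name, path in paths.items():
        print(f"wrote {name:18s} {path.name} ({path.stat().st_size} bytes)")

    corpus = read_tweets(paths["tweets"])
    tracts = load_tracts(paths["tracts"])
    ses = pd.read_csv(paths["ses"], dtype={"tract_id": str})
    result = run_pipeline(
        corpus,
        tracts,
        ses,
        load_food_lexicon(paths["food_lexicon"]),
        load_sentiment_lexicon(paths["sentiment_lexicon"]),
    )
    out = Path(tmp) / "analysis_table.csv"
    result.analysis_table.to_csv(out, index=False)
    print(f"\nanalysis table: {result.analysis_table.shape[0]} tracts x "
          f"{result.analysis_table.shape[1]} columns -> {out.name}")
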