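#!/usr/bin/env python
"""Rank single TimeFeats features by four-state decoding accuracy.

For each of the 41 features, classifies the four states across subjects
using only that feature's spatial-unit columns (single 85/15 split, the
fast mode), and compares against the full set and the band-power benchmark.
Requires the tables from 02_extract_features.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from statefeats import classify as clf
from statefeats.io import read_feature_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def _accuracy(table: clf.FeatureTable, mode: str = "global") -> float:
    plan = clf.build_folds(table, "across", holdout_fraction=0.15, seed=SEED)
    res = clf.run_classification(table, plan, clf.ClassifierConfig(pca_mode=mode), seed=SEED)
    return res.pooled_accuracy


def _restrict_columns(table: clf.FeatureTable, feature: str) -> clf.FeatureTable:
    cols = table.feature_blocks()[feature]
    return clf.FeatureTable(
        table.X[:, cols], table.y, table.subject, table.epoch_order,
        [table.column_meta[c] for c in cols],
    )


def main() -> None:
    table = read_feature_table(RESULTS / "features_timefeats.csv")
    rows = [{"feature": "full_set", "balanced_accuracy": round(_accuracy(table, "per_feature"), 3)}]
    for feature in table.feature_names:
        acc = _accuracy(_restrict_columns(table, feature))
        rows.append({"feature": feature, "balanced_accuracy": round(acc, 3)})
    fb = read_feature_table(RESULTS / "features_freqbands.csv")
    rows.append({"feature": "power_freqbands", "balanced_accuracy": round(_accuracy(fb), 3)})

    df = pd.DataFrame(rows).sort_values("balanced_accuracy", ascending=False)
    out = RESULTS / "single_feature_accuracy.csv"
    df.to_csv(out, index=False)
    print(df.head(12).to_string(index=False))
    print(f"\nwrote {out}")
    singles = df[~df.feature.isin(["full_set", "power_freqbands"])]
    print("best single feature:", singles.iloc[0]["feature"],
          singles.iloc[0]["balanced_accuracy"])


if __name__ == "__main__":
    main()
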