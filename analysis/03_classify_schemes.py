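#!/usr/bin/env python
"""Compare feature-set informativeness under the three partition schemes.

For every feature set (TimeFeats, FreqBands, fullFFT) and every scheme
(within, between, across), runs the cross-validated SVM and tabulates
balanced accuracy for the four-state problem and the two two-state
contrasts (EC/EO, BSL/VS). Requires the tables from 02_extract_features.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from statefeats import classify as clf
from statefeats.io import read_feature_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0
CLASS_SETS = {
    "all4": ("EC", "EO", "BSL", "VS"),
    "ec-eo": ("EC", "EO"),
    "bsl-vs": ("BSL", "VS"),
}


def main() -> None:
    rows = []
    for name in ("timefeats", "freqbands", "fullfft"):
        table_full = read_feature_table(RESULTS / f"features_{name}.csv")
        for classes, states in CLASS_SETS.items():
            table = clf.select_classes(table_full, states)
            for scheme, folds, mode in (
                ("within", 5, "global"),
                ("between", 10, "global"),
                ("across", 10, "per_feature"),
            ):
                plan = clf.build_folds(table, scheme, n_folds=folds, seed=SEED)
                res = clf.run_classification(
                    table, plan, clf.ClassifierConfig(pca_mode=mode), seed=SEED
                )
                rows.append({
                    "feature_set": name,
                    "classes": classes,
                    "scheme": scheme,
                    "mean_balanced_accuracy": round(float(np.mean(res.fold_accuracies)), 3),
                    "pooled_balanced_accuracy": round(res.pooled_accuracy, 3),
                    "n_folds": len(res.fold_accuracies),
                })
    df = pd.DataFrame(rows)
    out = RESULTS / "accuracy_by_scheme.csv"
    df.to_csv(out, index=False)
    print(df.pivot_table(index=["classes", "scheme"], columns="feature_set",
                         values="mean_balanced_accuracy").round(3).to_string())
    print(f"\nwrote {out}")
    four = df[df.classes == "all4"].pivot_table(index="scheme", columns="feature_set",
                                                values="mean_balanced_accuracy")
    best = four.idxmax(axis=1)
    print("best set per scheme (four-state):", dict(best))


if __name__ == "__main__":
    main()
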