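#!/usr/bin/env python
"""Extract the three feature sets from the simulated cohort.

TimeFeats (41 time-series descriptors), FreqBands (mean power in six
canonical bands) and fullFFT (power at 1..100 Hz) per epoch and spatial
unit. Requires results/cohort.h5 from 01_simulate_cohort.py.
"""

from pathlib import Path

import numpy as np

from statefeats.classify import assemble_feature_table
from statefeats.io import read_epochs

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_epochs(RESULTS / "cohort.h5")
    for name in ("TimeFeats", "FreqBands", "fullFFT"):
        table = assemble_feature_table(cohort, name)
        out = RESULTS / f"features_{name.lower()}.csv"
        table.to_dataframe().to_csv(out, index=False)
        nan_frac = float(np.isnan(table.X).mean())
        print(f"{name}: {table.X.shape[0]} epochs x {table.X.shape[1]} columns "
              f"({len(table.feature_names)} features x {table.X.shape[1] // len(table.feature_names)} units), "
              f"NaN fraction {nan_frac:.4f} -> {out.name}")


if __name__ == "__main__":
    main()
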