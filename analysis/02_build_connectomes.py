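#!/usr/bin/env python
"""Stage 2 — build per-subject connectomes.

FC: Pearson correlation of node time series, phase-surrogate significance
thresholding (p >= .05 edges zeroed), Fisher r-to-z, then a sign split into
FC_pos / FC_neg.  SC: log10(1 + w) compression of the streamline weights.
Writes connectomes to scratch/ and an edge-density summary to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from connage.fc import build_fc
from connage.io import load_cohort, save_matrix
from connage.sc import sc_transform

N_SURROGATES = 199
ALPHA = 0.05
SEED = 21

COHORT = Path("scratch/analysis/cohort")
OUT = Path("scratch/analysis/connectomes")
RESULTS = Path("results")


def main() -> None:
    cohort = load_cohort(COHORT)
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    iu = np.triu_indices(len(cohort.parcellation), k=1)
    rows = []
    for sid, ts, w in zip(cohort.subjects.index, cohort.timeseries, cohort.sc_weights):
        fcpos, fcneg, _ = build_fc(ts, n_surrogates=N_SURROGATES, alpha=ALPHA, rng=rng)
        sc = sc_transform(w)
        for kind, m in (("FCpos", fcpos), ("FCneg", fcneg), ("SC", sc)):
            save_matrix(OUT / f"{sid}_{kind}.npy", m)
        rows.append(
            {
                "subject_id": sid,
                "fc_pos_density": float((fcpos.values[iu] > 0).mean()),
                "fc_neg_density": float((fcneg.values[iu] > 0).mean()),
                "sc_density": float((sc.values[iu] > 0).mean()),
            }
        )
    density = pd.DataFrame(rows).set_index("subject_id")
    RESULTS.mkdir(exist_ok=True)
    density.describe().loc[["mean", "std", "min", "max"]].to_csv(
        RESULTS / "connectome_density.tsv", sep="\t"
    )
    print(f"connectomes for {len(rows)} subjects -> {OUT}")
    print(density.mean().round(3))


if __name__ == "__main__":
    main()
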