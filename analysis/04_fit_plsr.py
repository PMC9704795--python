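#!/usr/bin/env python
"""Stage 4 — PLS regression of age on the predictor block.

Residualizes predictors for sex and education, runs leave-one-out
cross-validation over component depths, selects the depth by the
sign-randomization test (alpha = .01), compares against scrambled null
models, and validates with repeated 80/20 train/test splits.  Writes the
model-validation table (per depth: LOO RMSEP, % predictor variance used,
% age variance explained, held-out r) to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from connage.io import load_table, save_json, save_table
from connage.pipeline import ensemble_summary_table
from connage.plsr import (
    loo_rmsep,
    residualize,
    repeated_splits,
    scrambled_null,
    select_ncomponents,
)

MAX_COMPONENTS = 6
ALPHA = 0.01
N_NULL = 100
N_SPLITS = 200
TRAIN_FRACTION = 0.8
SEED = 23

DATA = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    X = load_table(DATA / "features.tsv")
    subjects = load_table(DATA / "cohort/subjects.tsv").loc[X.index]
    covs = pd.DataFrame(
        {
            "sex": (subjects["sex"] == "M").astype(float),
            "education": subjects["education"].astype(float),
        }
    )
    Xr = residualize(X, covs)
    y = subjects["age"].to_numpy(dtype=float)
    rng = np.random.default_rng(SEED)

    cv = loo_rmsep(Xr, y, max_components=MAX_COMPONENTS)
    k = select_ncomponents(cv, alpha=ALPHA, rng=rng)
    k_fit = max(k, 1)
    print(f"selected {k} components; LOO RMSEP by depth: {np.round(cv.rmsep, 2)}")

    null_rmsep = np.empty(N_NULL)
    for b in range(N_NULL):
        Xn, yn = scrambled_null(Xr, y, rng)
        null_rmsep[b] = loo_rmsep(Xn, yn, max_components=k_fit).rmsep[k_fit]
    print(
        f"real RMSEP {cv.rmsep[k_fit]:.2f} vs null {null_rmsep.mean():.2f} "
        f"(sd {null_rmsep.std():.2f})"
    )

    ensemble = repeated_splits(
        Xr, y, n_components=k_fit, train_fraction=TRAIN_FRACTION, n_reps=N_SPLITS, rng=rng
    )
    summary = ensemble_summary_table(cv, null_rmsep, ensemble)
    RESULTS.mkdir(exist_ok=True)
    save_table(RESULTS / "model_summary.tsv", summary)
    save_json(
        RESULTS / "cv_report.json",
        {
            "rmsep": cv.rmsep,
            "x_variance_pct": cv.x_variance_pct,
            "y_variance_pct": cv.y_variance_pct,
            "selected_components": k,
        },
    )
    save_table(DATA / "residualized_features.tsv", Xr)
    np.save(DATA / "split_loadings.npy", ensemble.loadings)
    print(summary.round(3))


if __name__ == "__main__":
    main()
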