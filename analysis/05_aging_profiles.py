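#!/usr/bin/env python
"""Stage 5 — aging profiles.

Refits the reference model on the full sample (components oriented so score-
age correlations are negative: positive loadings then mean lower values at
higher age), aligns the repeated-split models to it (component order and
sign), and averages the per-split loadings into component-wise aging
profiles.  Writes per-component predictor loadings, network-wise means, the
frontal-vs-rest contrast for intra-network SC, and the component-age
correlations to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from connage.io import load_json, load_table, save_json, save_table
from connage.plsr import nipals_fit, repeated_splits
from connage.profiles import (
    align_signs,
    component_age_correlation,
    frontal_vs_rest_test,
    mean_loadings,
    network_mean_loadings,
    orient_reference,
)

N_SPLITS = 200
SEED = 24

DATA = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    Xr = load_table(DATA / "residualized_features.tsv")
    tags = load_table(DATA / "feature_tags.tsv")
    subjects = load_table(DATA / "cohort/subjects.tsv").loc[Xr.index]
    y = subjects["age"].to_numpy(dtype=float)
    k_fit = max(load_json(RESULTS / "cv_report.json")["selected_components"], 1)

    reference = orient_reference(nipals_fit(Xr, y, k_fit))
    ensemble = repeated_splits(
        Xr, y, n_components=k_fit, n_reps=N_SPLITS, rng=np.random.default_rng(SEED)
    )
    aligned = align_signs(ensemble, reference)
    profiles = mean_loadings(aligned, Xr.columns)
    age_corr = component_age_correlation(reference, y)

    metrics = {"component_age_correlations": [list(rp) for rp in age_corr]}
    for prof, (r, p) in zip(profiles, age_corr):
        save_table(RESULTS / f"profile_component{prof.component}.tsv", prof.loadings.join(tags))
        save_table(
            RESULTS / f"network_loadings_component{prof.component}.tsv",
            network_mean_loadings(prof, tags),
        )
        print(
            f"component {prof.component}: COG loading {prof.cog_mean:.3f} "
            f"({prof.cog_sd:.3f}), score-age r = {r:.2f} (p = {p:.2g})"
        )
    t, p = frontal_vs_rest_test(profiles[0], tags, kind="SC", scope="intra")
    metrics["frontal_vs_rest_sc_intra"] = {"t": t, "p": p}
    print(f"component 1 frontal-vs-rest intra-network SC: t = {t:.2f}, p = {p:.2g}")
    save_json(RESULTS / "profile_metrics.json", metrics)


if __name__ == "__main__":
    main()
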