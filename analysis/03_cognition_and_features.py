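#!/usr/bin/env python
"""Stage 3 — cognition composite and the predictor block.

Screens and stratum-median-imputes the 16-test battery, excludes +/-3 SD
outliers, checks KMO sampling adequacy, extracts the first-PC cognition score
(COG, higher = better), then reduces every subject's three connectomes to the
six node-wise strength estimates and assembles the subjects x (6N + COG)
predictor block.
"""

from pathlib import Path

from connage.cognition import cognition_pipeline
from connage.features import assemble_features
from connage.io import load_cohort, load_connectivity, save_json, save_table

COHORT = Path("scratch/analysis/cohort")
CONNECTOMES = Path("scratch/analysis/connectomes")
OUT = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    cohort = load_cohort(COHORT)
    cog = cognition_pipeline(cohort.battery, cohort.subjects["sex"], cohort.subjects["age"])
    print(
        f"COG: {len(cog.retained)}/{len(cohort.subjects)} subjects retained, "
        f"KMO={cog.kmo:.3f}, first PC explains {100 * cog.explained_variance_ratio:.1f}%"
    )
    mats = {
        sid: {
            kind: load_connectivity(CONNECTOMES / f"{sid}_{kind}.npy", kind)
            for kind in ("SC", "FCpos", "FCneg")
        }
        for sid in cog.retained
    }
    block = assemble_features(mats, cohort.parcellation, cog=cog.scores)
    save_table(OUT / "features.tsv", block.data)
    save_table(OUT / "feature_tags.tsv", block.tags)
    RESULTS.mkdir(exist_ok=True)
    save_table(RESULTS / "cog_loadings.tsv", cog.loadings.to_frame())
    save_json(
        RESULTS / "cognition_metrics.json",
        {
            "kmo": cog.kmo,
            "explained_variance_ratio": cog.explained_variance_ratio,
            "n_retained": int(len(cog.retained)),
        },
    )
    print(f"predictor block: {block.data.shape[0]} subjects x {block.n_predictors} predictors")


if __name__ == "__main__":
    main()
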