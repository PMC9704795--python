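"""Planted-structure validation experiments.

These routines run the study's own validity checks on synthetic cohorts whose
ground truth is known: whether the component-selection procedure recovers the
planted dimensionality, whether aligned mean loadings recover the planted
loading patterns, how far the real model's cross-validated error sits below
scrambled null models, and whether the phase-surrogate edge test controls its
type-I error on autocorrelated but independent signals.  They are used by the
test suite, the analysis drivers and the acceptance script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .fc import edge_significance
from .plsr import (
    loo_rmsep,
    nipals_fit,
    repeated_splits,
    residualize,
    scrambled_null,
    select_ncomponents,
)
from .profiles import align_signs, mean_loadings, orient_reference
from .synthetic import FeatureCohort, _ar1, simulate_feature_cohort


def _residualized(cohort: FeatureCohort) -> tuple[np.ndarray, np.ndarray]:
    covs = np.column_stack(
        [(cohort.sex == "M").astype(float), cohort.education.astype(float)]
    )
    return residualize(cohort.X.to_numpy(dtype=float), covs), cohort.age


def component_recovery(
    n_seeds: int = 50,
    n_subjects: int = 300,
    n_nodes: int = 100,
    max_components: int = 10,
    alpha: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Fraction of synthetic cohorts whose planted component count is selected.

    For each seed a feature-level cohort with the default two planted
    components is generated, residualized for sex/education, cross-validated
    by LOO and subjected to the sign-randomization depth selection.
    """
    selected = []
    for s in range(n_seeds):
        cohort = simulate_feature_cohort(n_subjects, n_nodes=n_nodes, seed=base_seed + s)
        X, y = _residualized(cohort)
        cv = loo_rmsep(X, y, max_components=max_components)
        selected.append(
            select_ncomponents(cv, alpha=alpha, rng=np.random.default_rng(base_seed + 10_000 + s))
        )
    truth_k = cohort.truth.n_components
    rate = float(np.mean([k == truth_k for k in selected]))
    return {"selected": selected, "n_components_true": truth_k, "recovery_rate": rate}


def loading_recovery(
    n_subjects: int = 300,
    n_nodes: int = 100,
    n_reps: int = 200,
    seed: int = 0,
) -> dict:
    """Correlation of aligned mean split loadings with the planted loadings.

    Components are matched greedily (profile component a vs planted pattern
    with maximal |corr|, one-to-one); returns per-component correlations and
    their minimum.
    """
    cohort = simulate_feature_cohort(n_subjects, n_nodes=n_nodes, seed=seed)
    X, y = _residualized(cohort)
    k = cohort.truth.n_components
    reference = orient_reference(nipals_fit(X, y, k))
    ensemble = repeated_splits(
        X, y, n_components=k, n_reps=n_reps, rng=np.random.default_rng(seed + 1)
    )
    aligned = align_signs(ensemble, reference)
    profiles = mean_loadings(aligned, list(cohort.X.columns))
    planted = np.asarray(cohort.truth.component_loadings)
    corr = np.zeros((k, k))
    for a, prof in enumerate(profiles):
        m = prof.loadings["mean"].to_numpy()
        for b in range(k):
            corr[a, b] = abs(np.corrcoef(m, planted[b])[0, 1])
    matched = []
    free = set(range(k))
    for a in range(k):
        b = max(free, key=lambda bb: corr[a, bb])
        matched.append(float(corr[a, b]))
        free.remove(b)
    return {"correlations": matched, "min_correlation": float(min(matched))}


def null_separation(
    n_subjects: int = 300,
    n_nodes: int = 100,
    n_null: int = 200,
    seed: int = 0,
) -> dict:
    """Real-model LOO RMSEP vs the distribution over scrambled null models.

    Null models permute every predictor column and the response independently;
    each is cross-validated at the same depth as the real model (the planted
    component count).
    """
    cohort = simulate_feature_cohort(n_subjects, n_nodes=n_nodes, seed=seed)
    X, y = _residualized(cohort)
    k = cohort.truth.n_components
    real = float(loo_rmsep(X, y, max_components=k).rmsep[k])
    rng = np.random.default_rng(seed + 1)
    nulls = np.empty(n_null)
    for b in range(n_null):
        Xn, yn = scrambled_null(X, y, rng)
        nulls[b] = loo_rmsep(Xn, yn, max_components=k).rmsep[k]
    return {
        "real_rmsep": real,
        "null_rmsep_mean": float(nulls.mean()),
        "null_rmsep_p1": float(np.percentile(nulls, 1.0)),
        "real_below_p1": bool(real < np.percentile(nulls, 1.0)),
        "null_rmsep": nulls,
    }


def surrogate_type_i(
    n_nodes: int = 32,
    n_timepoints: int = 296,
    phi: float = 0.5,
    n_surrogates: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    ci_level: float = 0.99,
) -> dict:
    """Type-I error of the surrogate edge test on independent AR(1) nodes.

    All node series are independent AR(1) signals (autocorrelated like BOLD,
    but with no cross-node coupling), so every retained edge is a false
    positive.  Returns the retained-edge fraction together with the binomial
    interval around alpha for the realized edge count.
    """
    rng = np.random.default_rng(seed)
    ts = _ar1(n_nodes, n_timepoints, phi, rng)
    _, mask, _ = edge_significance(ts, n_surrogates=n_surrogates, alpha=alpha, rng=rng)
    iu = np.triu_indices(n_nodes, k=1)
    n_edges = iu[0].size
    frac = float(mask[iu].mean())
    zc = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = zc * np.sqrt(alpha * (1 - alpha) / n_edges)
    return {
        "retained_fraction": frac,
        "n_edges": int(n_edges),
        "alpha": alpha,
        "ci_low": float(alpha - half),
        "ci_high": float(alpha + half),
        "within_ci": bool(alpha - half <= frac <= alpha + half),
    }
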