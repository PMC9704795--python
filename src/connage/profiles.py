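"""Aging profiles: aggregation of per-split PLS loadings into interpretable
component-wise summaries.

PLS component signs (and, across resamples, component order) are arbitrary:
flipping a component's weight/loading/score triple leaves predictions
unchanged.  Before averaging loadings across the split ensemble, every
split's components are therefore matched to a full-sample reference model
(greedy one-to-one matching on absolute loading correlation) and sign-flipped
to agree with it.

Orientation convention: the reference components are flipped so that each
score vector correlates non-positively with age (equivalently, y-loading
q_a <= 0).  Under this single global rule a *positive* predictor loading
means the predictor's value is lower at higher age (age-related decrease),
and the cognition loading comes out positive when performance declines with
age — the convention used for all reported profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import COG_COLUMN, FAMILIES
from .plsr import PLSModel, SplitEnsemble

MATCH_AMBIGUITY_TOL = 1e-6


@dataclass
class AgingProfile:
    """One component's full predictor-loading pattern across the ensemble."""

    component: int  # 1-based
    loadings: pd.DataFrame  # index predictor; columns mean, sd
    cog_mean: float | None
    cog_sd: float | None
    age_correlation: float | None = None
    age_correlation_p: float | None = None


def orient_reference(model: PLSModel, y=None) -> PLSModel:
    """Flip components (in place) so every score-age correlation is <= 0.

    With age as the response, corr(t_a, age) has the sign of the y-loading
    q_a, so the rule is q_a <= 0; ``y`` is accepted for an explicit
    correlation check when scores/response are available.
    """
    for a in range(model.n_components):
        if y is not None:
            flip = np.corrcoef(model.scores[:, a], np.asarray(y, dtype=float))[0, 1] > 0
        else:
            flip = model.y_loadings[a] > 0
        if flip:
            model.flip_component(a)
    return model


def _match_components(rep_loadings: np.ndarray, ref_loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of rep components to reference components.

    Returns (order, signs): rep component ``order[a]`` matches reference
    component ``a``, to be multiplied by ``signs[a]``.
    """
    k = ref_loadings.shape[1]
    c = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            c[a, b] = np.corrcoef(ref_loadings[:, a], rep_loadings[:, b])[0, 1]
    c = np.nan_to_num(c)
    order = np.full(k, -1)
    signs = np.ones(k)
    absc = np.abs(c)
    free_ref = set(range(k))
    free_rep = set(range(k))
    for _ in range(k):
        best = -1.0
        pick = None
        ambiguous = False
        for a in free_ref:
            for b in free_rep:
                if absc[a, b] > best + MATCH_AMBIGUITY_TOL:
                    best = absc[a, b]
                    pick = (a, b)
                    ambiguous = False
                elif pick is not None and abs(absc[a, b] - best) <= MATCH_AMBIGUITY_TOL and (a, b) != pick:
                    ambiguous = True
        if ambiguous:
            warnings.warn(
                "ambiguous component matching; falling back to index order",
                RuntimeWarning,
                stacklevel=3,
            )
            order = np.arange(k)
            signs = np.array([1.0 if c[a, a] >= 0 else -1.0 for a in range(k)])
            return order, signs
        a, b = pick
        order[a] = b
        signs[a] = 1.0 if c[a, b] >= 0 else -1.0
        free_ref.remove(a)
        free_rep.remove(b)
    return order, signs


def align_signs(ensemble: SplitEnsemble, reference: PLSModel) -> SplitEnsemble:
    """Align every split's components (order and sign) to the reference model.

    Returns a new ensemble; weights, loadings and y-loadings are permuted and
    flipped jointly, so each split's predictions are untouched.
    """
    if reference.n_components != ensemble.n_components:
        raise ValueError("reference depth differs from ensemble depth")
    loadings = ensemble.loadings.copy()
    weights = ensemble.weights.copy()
    y_loadings = ensemble.y_loadings.copy()
    ref = reference.x_loadings
    for rep in range(ensemble.n_reps):
        order, signs = _match_components(loadings[rep], ref)
        loadings[rep] = loadings[rep][:, order] * signs
        weights[rep] = weights[rep][:, order] * signs
        y_loadings[rep] = y_loadings[rep][order] * signs
    return replace(ensemble, loadings=loadings, weights=weights, y_loadings=y_loadings)


def mean_loadings(
    ensemble: SplitEnsemble, predictor_names: list[str] | pd.Index
) -> list[AgingProfile]:
    """Per-component mean and SD of every predictor's loading across splits.

    The COG predictor's loading is carried in the table and surfaced
    separately on the profile.
    """
    names = pd.Index(predictor_names)
    if len(names) != ensemble.loadings.shape[1]:
        raise ValueError("predictor_names length differs from loading dimension")
    profiles = []
    for a in range(ensemble.n_components):
        block = ensemble.loadings[:, :, a]  # (n_reps, p)
        table = pd.DataFrame(
            {"mean": block.mean(axis=0), "sd": block.std(axis=0, ddof=0)}, index=names
        )
        cog_mean = float(table.at[COG_COLUMN, "mean"]) if COG_COLUMN in names else None
        cog_sd = float(table.at[COG_COLUMN, "sd"]) if COG_COLUMN in names else None
        profiles.append(
            AgingProfile(component=a + 1, loadings=table, cog_mean=cog_mean, cog_sd=cog_sd)
        )
    return profiles


def network_mean_loadings(profile: AgingProfile, tags: pd.DataFrame) -> pd.DataFrame:
    """Network-wise averages of node mean loadings, per predictor family.

    Returns a network x family table (columns like ``SC_intra`` ...); the
    average is unweighted over all nodes of the network, computed separately
    for each of the six (kind, scope) families.  The COG predictor belongs to
    no network and is excluded.
    """
    merged = profile.loadings.join(tags, how="inner")
    conn = merged.dropna(subset=["network"])
    out = {}
    for kind, scope in FAMILIES:
        fam = conn[(conn["kind"] == kind) & (conn["scope"] == scope)]
        out[f"{kind}_{scope}"] = fam.groupby("network")["mean"].mean()
    return pd.DataFrame(out)


def frontal_vs_rest_test(
    profile: AgingProfile,
    tags: pd.DataFrame,
    kind: str = "SC",
    scope: str = "intra",
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test of node mean loadings, frontal vs rest.

    Node-level mean loadings of one predictor family are the observations;
    pooled-variance by default, Welch via ``welch=True``.
    """
    merged = profile.loadings.join(tags, how="inner")
    fam = merged[(merged["kind"] == kind) & (merged["scope"] == scope)]
    frontal = fam.loc[fam["lobe"] == "frontal", "mean"].to_numpy()
    rest = fam.loc[fam["lobe"] == "other", "mean"].to_numpy()
    if frontal.size < 2 or rest.size < 2:
        raise ValueError(
            f"both lobe groups need >= 2 nodes (frontal={frontal.size}, rest={rest.size})"
        )
    t, p = stats.ttest_ind(frontal, rest, equal_var=not welch)
    return float(t), float(p)


def component_age_correlation(model: PLSModel, age) -> list[tuple[float, float]]:
    """Pearson r (with p-value) between each component's scores and age."""
    age = np.asarray(age, dtype=float)
    out = []
    for a in range(model.n_components):
        r, p = stats.pearsonr(model.scores[:, a], age)
        out.append((float(r), float(p)))
    return out
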