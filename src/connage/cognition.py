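"""Cognition composite: screening, imputation, KMO and the PCA-based COG score.

A 16-test neuropsychological battery is reduced to one global performance
score (COG).  Order of operations, fixed:

1. screen: subjects with three or more missing test scores are excluded;
2. impute: remaining missing entries are replaced by the median of the
   subject's sex x age-decade stratum (decades 55-64, 65-74, 75-84, 85+);
3. outlier exclusion: any score outside mean +/- 3 SD (per test, on the
   screened sample) excludes the subject;
4. KMO sampling adequacy of the cleaned battery;
5. PCA on the correlation matrix (tests are standardized — their native units
   are incommensurate); COG is the first principal component score,
   standardized, with the sign fixed so the majority of test loadings are
   positive (higher COG = better performance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

DECADE_EDGES = (65.0, 75.0, 85.0)
DECADE_LABELS = ("55-64", "65-74", "75-84", "85+")
MAX_MISSING = 2
OUTLIER_SD = 3.0


@dataclass
class CogComposite:
    """COG scores plus the PCA diagnostics behind them."""

    scores: pd.Series  # standardized, higher = better performance
    loadings: pd.Series  # unit-norm first-PC loadings per test
    explained_variance_ratio: float
    kmo: float
    retained: pd.Index  # subjects surviving screening + outlier exclusion


def age_decade(age: pd.Series | np.ndarray) -> pd.Series:
    """Age-decade stratum labels (55-64 / 65-74 / 75-84 / 85+).

    Ages below 55 fall into the first stratum; the cohort design starts at 55.
    """
    age = pd.Series(np.asarray(age, dtype=float)) if not isinstance(age, pd.Series) else age
    idx = np.digitize(age.to_numpy(dtype=float), DECADE_EDGES)
    return pd.Series(np.asarray(DECADE_LABELS)[idx], index=age.index, name="decade")


def screen_and_impute(
    battery: pd.DataFrame, sex: pd.Series, age: pd.Series
) -> pd.DataFrame:
    """Drop subjects with >= 3 missing scores; stratum-median-impute the rest.

    The imputation stratum is (sex, age decade); an empty stratum for a needed
    (stratum, test) median raises, naming the stratum.
    """
    if not battery.index.equals(sex.index) or not battery.index.equals(age.index):
        raise ValueError("battery, sex and age must share the same subject index")
    n_missing = battery.isna().sum(axis=1)
    kept = battery.loc[n_missing <= MAX_MISSING].copy()
    strata = pd.DataFrame({"sex": sex.loc[kept.index], "decade": age_decade(age.loc[kept.index])})
    if not kept.isna().any().any():
        return kept
    medians = kept.groupby([strata["sex"], strata["decade"]], observed=True).median()
    for subject in kept.index[kept.isna().any(axis=1)]:
        key = (strata.at[subject, "sex"], strata.at[subject, "decade"])
        for test in kept.columns[kept.loc[subject].isna()]:
            try:
                value = medians.loc[key, test]
            except KeyError:
                value = np.nan
            if pd.isna(value):
                raise ValueError(
                    f"empty stratum sex={key[0]!r}, decade={key[1]!r} for test {test!r}"
                )
            kept.at[subject, test] = value
    return kept


def exclude_outliers(battery: pd.DataFrame, n_sd: float = OUTLIER_SD) -> pd.Index:
    """Subjects whose every score lies within mean +/- n_sd SD (per test).

    SD is computed on the supplied (screened, imputed) sample; a zero-variance
    test excludes nobody.
    """
    if len(battery) < 3:
        raise ValueError("need at least 3 subjects for outlier screening")
    if battery.isna().any().any():
        raise ValueError("outlier screening expects a complete battery (impute first)")
    mean = battery.mean(axis=0)
    sd = battery.std(axis=0, ddof=1)
    lo = mean - n_sd * sd
    hi = mean + n_sd * sd
    ok = ((battery.ge(lo) & battery.le(hi)) | (sd == 0)).all(axis=1)
    return battery.index[ok]


def kmo(battery: pd.DataFrame) -> float:
    """Kaiser-Meyer-Olkin sampling-adequacy index of the battery.

    Overall KMO = sum(r_ij^2) / (sum(r_ij^2) + sum(q_ij^2)) over i != j, where
    r are observed correlations and q the anti-image partial correlations
    obtained from the inverse correlation matrix.  Scale-free by construction.
    """
    x = battery.to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    if np.linalg.cond(r) > 1e12:
        raise ValueError("singular correlation matrix; KMO undefined")
    inv = np.linalg.inv(r)
    d = np.sqrt(np.abs(np.diag(inv)))
    q = -inv / np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(q[off] ** 2)
    return float(r2 / (r2 + q2))


def pca_cog(battery: pd.DataFrame) -> tuple[pd.Series, pd.Series, float]:
    """First-PC composite of the standardized battery.

    Returns ``(scores, loadings, explained_variance_ratio)``; scores have zero
    mean and unit variance over the input subjects, loadings are the unit-norm
    first eigenvector with majority-positive sign.
    """
    if len(battery) < battery.shape[1]:
        raise ValueError(
            f"need at least as many subjects ({len(battery)}) as tests ({battery.shape[1]})"
        )
    x = battery.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        dead = battery.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance test(s): {dead}")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=1, svd_solver="full")
    raw = pca.fit_transform(z)[:, 0]
    loadings = pca.components_[0]
    sign = 1.0 if np.sum(loadings > 0) * 2 >= loadings.size else -1.0
    loadings = sign * loadings
    raw = sign * raw
    scores = (raw - raw.mean()) / raw.std(ddof=0)
    return (
        pd.Series(scores, index=battery.index, name="COG"),
        pd.Series(loadings, index=battery.columns, name="loading"),
        float(pca.explained_variance_ratio_[0]),
    )


def cognition_pipeline(
    battery: pd.DataFrame, sex: pd.Series, age: pd.Series
) -> CogComposite:
    """screen -> impute -> outlier-exclude -> KMO -> PCA, in that fixed order."""
    cleaned = screen_and_impute(battery, sex, age)
    retained = exclude_outliers(cleaned)
    cleaned = cleaned.loc[retained]
    adequacy = kmo(cleaned)
    scores, loadings, evr = pca_cog(cleaned)
    return CogComposite(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr,
        kmo=adequacy,
        retained=retained,
    )
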