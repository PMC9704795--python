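"""Synthetic cohort generator with planted, recoverable structure.

The reference cohort behind this analysis (older adults, 55-85 years, with
resting-state time series, streamline-weight SC matrices, and a 16-test
cognitive battery) is not publicly downloadable, so every pipeline stage is
exercised on synthetic cohorts whose generating model is stored alongside the
data (:class:`GroundTruth`) and can be tested for recovery.

Two levels of generation are provided:

* **raw level** — per-subject node x time BOLD-like series (network latent +
  global latent with age-modulated mixing + white noise), SC weight matrices
  (log-normal SIFT-2-like weights whose frontal-incident edges decline faster
  with age), and a cognitive battery driven by one latent factor coupled to
  age (default correlation -0.44) and education (+0.35).
* **feature level** — predictor blocks with explicitly planted latent
  components: X = sum_k scale_k * s_k v_k' + noise with age-informative
  scores s_k and stored loading vectors v_k.  This is the ground truth used
  for component-count and loading recovery tests.  The two default planted
  components share the age signal equally but differ in X-variance
  (scales 3 and 1): were both equal, a single predictive direction would
  absorb them and the planted dimensionality would not be identifiable by
  any method.

Ages are uniform on [55, 85] (maximizing identifiability at small n rather
than matching the reference cohort's age histogram), sexes balanced, and all
draws flow from one seed, so cohorts are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import COG_COLUMN, FAMILIES, feature_columns
from .parcellation import make_parcellation, validate_parcellation

AGE_RANGE = (55.0, 85.0)
#: SD of U(55, 85), used to express ages in z-units inside the generator.
AGE_Z_SD = (AGE_RANGE[1] - AGE_RANGE[0]) / np.sqrt(12.0)
AGE_Z_MEAN = (AGE_RANGE[0] + AGE_RANGE[1]) / 2.0

N_TESTS = 16
#: Fixed per-test factor loadings / offsets / scales of the battery
#: (test-native flavored units).
TEST_LOADINGS = np.linspace(0.9, 0.5, N_TESTS)
TEST_OFFSETS = 20.0 + 3.0 * np.arange(N_TESTS)
TEST_SCALES = np.linspace(2.0, 8.0, N_TESTS)


def zage(age) -> np.ndarray:
    """Age in generator z-units (mean 70, SD of the uniform design)."""
    return (np.asarray(age, dtype=float) - AGE_Z_MEAN) / AGE_Z_SD


@dataclass
class GroundTruth:
    """Generating parameters planted into a synthetic cohort.

    Stored with every cohort so recovery tests can compare estimates with the
    truth.  ``component_loadings`` (k x p over the canonical predictor
    columns, unit rows, mutually orthogonal) defines the feature-level
    planted components; the remaining fields parameterize the raw-level
    generators (rates per year of age, noise SDs in the respective signal
    units).
    """

    n_components: int = 2
    component_loadings: np.ndarray | None = None
    component_scale: tuple[float, ...] = (3.0, 1.0)
    score_noise_sd: float = 0.5
    feature_noise_sd: float = 0.05
    # cognition battery
    age_effect_cog: float = -0.44
    edu_effect_cog: float = 0.35
    cog_noise_sd: float = 0.6
    # SC generator
    frontal_decline_rate: float = 0.02
    nonfrontal_decline_ratio: float = 0.4
    sc_mu_intra: float = 1.0
    sc_mu_inter: float = 0.3
    sc_noise_sd: float = 0.5
    sc_density_intra: float = 0.8
    sc_density_inter: float = 0.4
    # time-series generator
    fc_intra_weight: float = 0.8
    fc_intra_age_slope: float = 0.005
    fc_inter_weight: float = 0.3
    fc_inter_age_slope: float = 0.006
    ts_noise_sd: float = 1.0
    latent_ar: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonfrontal_decline_ratio <= 1.0:
            raise ValueError(
                "nonfrontal_decline_ratio must be in [0, 1] so the frontal "
                "decline dominates in magnitude"
            )
        if self.component_loadings is not None:
            v = np.asarray(self.component_loadings, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError("component loadings must be finite")
            self.component_loadings = v
        if len(self.component_scale) < self.n_components:
            raise ValueError("component_scale shorter than n_components")

    @property
    def nonfrontal_decline_rate(self) -> float:
        return self.frontal_decline_rate * self.nonfrontal_decline_ratio

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["component_loadings"] is not None:
            d["component_loadings"] = np.asarray(d["component_loadings"]).tolist()
        d["component_scale"] = list(d["component_scale"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        if d.get("component_loadings") is not None:
            d["component_loadings"] = np.asarray(d["component_loadings"], dtype=float)
        d["component_scale"] = tuple(d.get("component_scale", (3.0, 1.0)))
        return cls(**d)


def _family_pattern(parc: pd.DataFrame, base: dict[tuple[str, str], float],
                    frontal_boost: dict[tuple[str, str], float] | None = None,
                    cog: float = 0.0) -> np.ndarray:
    """Signed pattern over the canonical 6N+1 predictor ordering."""
    n_nodes = len(parc)
    frontal = (parc["lobe"] == "frontal").to_numpy()
    out = np.zeros(6 * n_nodes + 1)
    for f_idx, fam in enumerate(FAMILIES):
        vals = np.full(n_nodes, base.get(fam, 0.0))
        if frontal_boost and fam in frontal_boost:
            vals = np.where(frontal, vals * frontal_boost[fam], vals)
        out[f_idx:-1:6] = vals
    out[-1] = cog
    return out


def default_component_loadings(parc: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Planted loading patterns over the canonical predictor columns.

    Component 1 emulates global aging: SC decline everywhere (frontal-
    emphasized), within-network positive FC decline, between-network positive
    FC increase, within-network anticorrelation increase, and cognitive
    decline.  Component 2 emulates frontal-only SC decline with globally
    rising FC and the strongest cognitive loading.  Component 3 (if
    requested) emulates preserved SC with globally low FC.  Patterns are
    Gram-Schmidt orthonormalized in sequence, so they are exactly orthogonal
    unit vectors.
    """
    if not 1 <= n_components <= 3:
        raise ValueError("default loadings are defined for 1..3 components")
    raw = [
        _family_pattern(
            parc,
            base={
                ("SC", "intra"): 1.0,
                ("SC", "inter"): 1.0,
                ("FCpos", "intra"): 1.0,
                ("FCpos", "inter"): -0.5,
                ("FCneg", "intra"): -0.5,
                ("FCneg", "inter"): 0.5,
            },
            frontal_boost={("SC", "intra"): 2.0, ("SC", "inter"): 2.0},
            cog=1.5,
        ),
        _family_pattern(
            parc,
            base={
                ("SC", "intra"): 0.0,
                ("SC", "inter"): 0.0,
                ("FCpos", "intra"): -1.0,
                ("FCpos", "inter"): -1.0,
                ("FCneg", "intra"): -0.5,
                ("FCneg", "inter"): -1.0,
            },
            frontal_boost=None,
            cog=2.0,
        ),
        _family_pattern(
            parc,
            base={
                ("SC", "intra"): -1.0,
                ("SC", "inter"): -1.0,
                ("FCpos", "intra"): 1.0,
                ("FCpos", "inter"): 1.5,
                ("FCneg", "inter"): 1.0,
            },
            frontal_boost=None,
            cog=1.0,
        ),
    ]
    # frontal-only SC decline for component 2
    frontal = (parc["lobe"] == "frontal").to_numpy()
    n_nodes = len(parc)
    for f_idx, fam in enumerate(FAMILIES):
        if fam in (("SC", "intra"), ("SC", "inter")):
            raw[1][f_idx:-1:6] = np.where(frontal, 1.5, 0.0)
    v = np.asarray(raw[:n_components])
    # Gram-Schmidt
    for k in range(v.shape[0]):
        for j in range(k):
            v[k] -= (v[k] @ v[j]) * v[j]
        norm = np.linalg.norm(v[k])
        if norm == 0:
            raise ValueError(f"degenerate planted pattern {k}")
        v[k] /= norm
    return v


def make_ground_truth(parc: pd.DataFrame, n_components: int = 2, **overrides) -> GroundTruth:
    """Ground truth with default planted loadings for this parcellation."""
    loadings = overrides.pop("component_loadings", None)
    if loadings is None:
        loadings = default_component_loadings(parc, n_components)
    return GroundTruth(n_components=n_components, component_loadings=loadings, **overrides)


# ---------------------------------------------------------------------------
# demographics


def simulate_demographics(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """Ages uniform on [55, 85], balanced sexes, education grades 3..10."""
    age = rng.uniform(*AGE_RANGE, size=n_subjects)
    sex = np.array(["F", "M"] * (n_subjects // 2 + 1))[:n_subjects]
    sex = sex[rng.permutation(n_subjects)]
    edu = np.clip(np.round(rng.normal(6.5, 1.9, size=n_subjects)), 3, 10).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_subjects)],
            "age": age,
            "sex": sex,
            "education": edu,
        }
    ).set_index("subject_id")


# ---------------------------------------------------------------------------
# raw-level generators


def _ar1(n_series: int, n_timepoints: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) latents (BOLD-like temporal smoothness)."""
    eps = rng.standard_normal((n_series, n_timepoints))
    if phi == 0:
        return eps
    out = np.empty_like(eps)
    innov_sd = np.sqrt(1.0 - phi**2)
    out[:, 0] = eps[:, 0]
    for t in range(1, n_timepoints):
        out[:, t] = phi * out[:, t - 1] + innov_sd * eps[:, t]
    return out


def simulate_timeseries(
    subject_age: float,
    parc: pd.DataFrame,
    truth: GroundTruth,
    n_timepoints: int = 296,
    rng: np.random.Generator | None = None,
    n_volumes: int | None = None,
    discard_volumes: int = 0,
) -> np.ndarray:
    """One subject's node x time BOLD-like matrix.

    Each node's signal is its network's shared latent plus a global
    cross-network latent plus white noise; the network-latent weight falls
    and the global-latent weight rises with age, so within-network
    correlation exceeds between-network correlation while their gap narrows
    in older subjects.  Passing ``n_volumes``/``discard_volumes`` emulates an
    acquisition in which the first volumes are discarded (300 volumes, 4
    discarded -> 296 columns).
    """
    if rng is None:
        rng = np.random.default_rng()
    validate_parcellation(parc)
    if n_volumes is not None:
        total = n_volumes
        if not 0 <= discard_volumes < n_volumes:
            raise ValueError("discard_volumes must be in [0, n_volumes)")
    else:
        total = n_timepoints + discard_volumes
    if total - discard_volumes < 32:
        raise ValueError("need at least 32 retained time points")

    networks = pd.unique(parc["network"])
    latents = _ar1(len(networks), total, truth.latent_ar, rng)
    global_latent = _ar1(1, total, truth.latent_ar, rng)[0]
    net_index = {net: k for k, net in enumerate(networks)}
    rows = np.array([net_index[n] for n in parc["network"]])

    years = subject_age - AGE_RANGE[0]
    w_intra = max(truth.fc_intra_weight - truth.fc_intra_age_slope * years, 0.05)
    w_inter = truth.fc_inter_weight + truth.fc_inter_age_slope * years
    signal = w_intra * latents[rows] + w_inter * global_latent
    signal = signal + truth.ts_noise_sd * rng.standard_normal(signal.shape)
    return signal[:, discard_volumes:]


def simulate_sc(
    subject_age: float,
    parc: pd.DataFrame,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One subject's symmetric non-negative streamline-weight matrix.

    Edge weights are log-normal around a family mean (within-network edges
    heavier than between-network ones) with a per-year exponential decline
    that is ``1 / nonfrontal_decline_ratio`` times faster for edges incident
    to a frontal node; a Bernoulli mask thins the graph to realistic density.
    """
    if rng is None:
        rng = np.random.default_rng()
    validate_parcellation(parc)
    if not AGE_RANGE[0] - 5 <= subject_age <= AGE_RANGE[1] + 5:
        raise ValueError(f"age {subject_age} outside the generator range")
    n = len(parc)
    networks = parc["network"].to_numpy()
    frontal = (parc["lobe"] == "frontal").to_numpy()
    same_net = networks[:, None] == networks[None, :]
    any_frontal = frontal[:, None] | frontal[None, :]

    years = subject_age - AGE_RANGE[0]
    mu = np.where(same_net, truth.sc_mu_intra, truth.sc_mu_inter)
    rate = np.where(any_frontal, truth.frontal_decline_rate, truth.nonfrontal_decline_rate)
    mu = mu - rate * years
    density = np.where(same_net, truth.sc_density_intra, truth.sc_density_inter)

    iu = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    vals = np.exp(mu[iu] + truth.sc_noise_sd * rng.standard_normal(iu[0].size))
    vals *= rng.random(iu[0].size) < density[iu]
    w[iu] = vals
    return w + w.T


def simulate_cognition(
    subject_age,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    education=None,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cognitive battery (16 tests) for one subject or a cohort.

    All tests share one latent performance factor g with population
    correlation ``age_effect_cog`` to age (and ``edu_effect_cog`` to
    education when supplied); each test adds unique noise and is mapped to
    test-native offsets/scales.  ``missing_rate`` injects missing entries
    completely at random (for imputation tests).

    Returns ``(battery, latent)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    age = np.atleast_1d(np.asarray(subject_age, dtype=float))
    n = age.size
    a = truth.age_effect_cog
    if education is not None:
        e = truth.edu_effect_cog
        zedu = (np.atleast_1d(np.asarray(education, dtype=float)) - 6.5) / 1.9
    else:
        e = 0.0
        zedu = 0.0
    resid_var = 1.0 - a**2 - e**2
    if resid_var < 0:
        raise ValueError("age and education effects imply negative residual variance")
    g = a * zage(age) + e * zedu + np.sqrt(resid_var) * rng.standard_normal(n)
    unique = truth.cog_noise_sd * rng.standard_normal((n, N_TESTS))
    scores = TEST_OFFSETS + TEST_SCALES * (TEST_LOADINGS * g[:, None] + unique)
    battery = pd.DataFrame(scores, columns=[f"test_{j + 1:02d}" for j in range(N_TESTS)])
    if missing_rate > 0:
        battery = battery.mask(rng.random(battery.shape) < missing_rate)
    return battery, g


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SyntheticCohort:
    """Raw-level cohort: demographics + battery + per-subject matrices."""

    subjects: pd.DataFrame  # index subject_id; age, sex, education, test_01..16
    timeseries: list[np.ndarray]
    sc_weights: list[np.ndarray]
    parcellation: pd.DataFrame
    truth: GroundTruth
    seed: int

    @property
    def battery(self) -> pd.DataFrame:
        return self.subjects.filter(like="test_")


def simulate_cohort(
    n_subjects: int,
    n_nodes: int = 100,
    seed: int = 0,
    truth: GroundTruth | None = None,
    parcellation: pd.DataFrame | None = None,
    n_timepoints: int = 296,
    missing_rate: float = 0.0,
) -> SyntheticCohort:
    """Generate a full raw-level cohort reproducibly from one seed."""
    rng = np.random.default_rng(seed)
    parc = make_parcellation(n_nodes) if parcellation is None else parcellation
    if truth is None:
        truth = make_ground_truth(parc)
    subjects = simulate_demographics(n_subjects, rng)
    battery, _ = simulate_cognition(
        subjects["age"].to_numpy(),
        truth,
        rng,
        education=subjects["education"].to_numpy(),
        missing_rate=missing_rate,
    )
    battery.index = subjects.index
    subjects = subjects.join(battery)
    ts, sc = [], []
    for age in subjects["age"]:
        ts.append(simulate_timeseries(age, parc, truth, n_timepoints=n_timepoints, rng=rng))
        sc.append(simulate_sc(age, parc, truth, rng=rng))
    return SyntheticCohort(subjects, ts, sc, parc, truth, seed)


@dataclass
class FeatureCohort:
    """Feature-level cohort with explicitly planted latent components."""

    X: pd.DataFrame  # subjects x (6N + 1) canonical predictor columns
    age: np.ndarray
    sex: np.ndarray
    education: np.ndarray
    scores: np.ndarray  # (n, k) planted latent scores
    truth: GroundTruth
    parcellation: pd.DataFrame

    @property
    def predictor_names(self) -> pd.Index:
        return self.X.columns


def simulate_feature_cohort(
    n_subjects: int,
    n_nodes: int = 100,
    seed: int = 0,
    truth: GroundTruth | None = None,
    parcellation: pd.DataFrame | None = None,
) -> FeatureCohort:
    """Predictor block with planted components: X = sum_k c_k s_k v_k' + E.

    Every planted score is the subject's z-scored age plus independent noise
    (``score_noise_sd``), so all components carry age information; the
    X-variance scales ``component_scale`` differ across components so the
    planted dimensionality is identifiable (see module docstring).
    """
    rng = np.random.default_rng(seed)
    parc = make_parcellation(n_nodes) if parcellation is None else parcellation
    if truth is None:
        truth = make_ground_truth(parc)
    v = truth.component_loadings
    if v is None:
        v = default_component_loadings(parc, truth.n_components)
    k, p = v.shape
    expected_p = 6 * len(parc) + 1
    if p != expected_p:
        raise ValueError(f"loadings cover {p} predictors, parcellation implies {expected_p}")
    demo = simulate_demographics(n_subjects, rng)
    z = zage(demo["age"].to_numpy())
    scores = z[:, None] + truth.score_noise_sd * rng.standard_normal((n_subjects, k))
    scales = np.asarray(truth.component_scale[:k])
    X = (scores * scales) @ v + truth.feature_noise_sd * rng.standard_normal((n_subjects, p))
    Xdf = pd.DataFrame(X, index=demo.index, columns=feature_columns(len(parc), with_cog=True))
    return FeatureCohort(
        X=Xdf,
        age=demo["age"].to_numpy(),
        sex=demo["sex"].to_numpy(),
        education=demo["education"].to_numpy(),
        scores=scores,
        truth=truth,
        parcellation=parc,
    )
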