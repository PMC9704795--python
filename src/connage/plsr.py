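"""NIPALS partial least squares regression of age on the predictor block.

The predictor block (COG + 6N connectivity strengths, corrected for sex and
education) typically has far more columns than subjects and is highly
collinear; PLS1 decomposes it into a small set of mutually orthogonal score
vectors maximally covarying with age and regresses age on those.  Model
complexity is chosen by leave-one-out cross-validation: the RMSEP curve over
candidate component counts is compared with a van der Voet style
sign-randomization test on the paired per-subject squared prediction errors,
and the smallest count not significantly worse (p >= alpha) than the global
RMSEP minimum is selected.

Validation utilities mirror the study design: scrambled null models (rows of
every predictor column and the response independently permuted, destroying
X-y and inter-column dependence while preserving marginals) and repeated
random train/test splits (default 80/20, 1000 repetitions) whose per-split
loadings feed the aging-profile aggregation.

Predictor columns are centered but not unit-scaled by default (the strengths
are commensurate after residualization); ``scale=True`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500
DEGENERATE_SS = 1e-300


def _as_array(x) -> np.ndarray:
    if isinstance(x, (pd.DataFrame, pd.Series)):
        return x.to_numpy(dtype=float)
    return np.asarray(x, dtype=float)


def residualize(X, covariates) -> np.ndarray:
    """Replace every predictor column by its least-squares residual on the
    covariates (plus intercept).

    ``covariates`` is an n x c array/frame (e.g. sex and education).  The
    response (age) is never touched by this step.
    """
    Xa = _as_array(X)
    C = _as_array(covariates)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != Xa.shape[0]:
        raise ValueError("covariates and X must have the same number of rows")
    design = np.column_stack([np.ones(C.shape[0]), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design (collinear covariates)")
    beta, *_ = np.linalg.lstsq(design, Xa, rcond=None)
    resid = Xa - design @ beta
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(resid, index=X.index, columns=X.columns)
    return resid


@dataclass
class PLSModel:
    """Fitted PLS1 factors.

    ``x_weights`` W, ``x_loadings`` P are p x k; ``y_loadings`` q has length
    k; ``scores`` T (n x k) are mutually orthogonal.  Predictions at any
    cumulative depth 1..k are reproducible from the stored factors.
    """

    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    x_scale: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]

    def predict_path(self, X) -> np.ndarray:
        """Predictions at every cumulative depth: returns (n, k) array where
        column a-1 uses components 1..a."""
        Xr = _as_array(X) - self.x_mean
        if self.x_scale is not None:
            Xr = Xr / self.x_scale
        n = Xr.shape[0]
        k = self.n_components
        out = np.empty((n, k))
        yhat = np.full(n, self.y_mean)
        for a in range(k):
            t = Xr @ self.x_weights[:, a]
            yhat = yhat + self.y_loadings[a] * t
            Xr = Xr - np.outer(t, self.x_loadings[:, a])
            out[:, a] = yhat
        return out

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        k = self.n_components if n_components is None else n_components
        if not 0 <= k <= self.n_components:
            raise ValueError(f"n_components must be in 0..{self.n_components}")
        if k == 0:
            return np.full(_as_array(X).shape[0], self.y_mean)
        return self.predict_path(X)[:, k - 1]

    def flip_component(self, a: int) -> None:
        """Jointly flip the sign of component ``a``'s weight/loading/score;
        predictions are invariant under this."""
        self.x_weights[:, a] *= -1.0
        self.x_loadings[:, a] *= -1.0
        self.y_loadings[a] *= -1.0
        self.scores[:, a] *= -1.0


def nipals_fit(
    X,
    y,
    n_components: int,
    scale: bool = False,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> PLSModel:
    """Fit PLS1 by NIPALS with deflation after every component.

    X and y are centered internally (optionally X is unit-scaled).  For a
    univariate response the weight iteration has a closed fixed point, but the
    iteration is run to the stated tolerance regardless; failure to converge
    within ``max_iter`` raises, naming the component.
    """
    Xa = _as_array(X)
    ya = _as_array(y).ravel()
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in 1..min(n-1, p)={min(n - 1, p)}")
    x_mean = Xa.mean(axis=0)
    Xc = Xa - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    y_mean = float(ya.mean())
    yc = ya - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm**2 <= DEGENERATE_SS:
            raise ValueError(
                f"component {a + 1}: X carries no remaining covariance with y "
                "(rank exhausted)"
            )
        w /= norm
        for _ in range(max_iter):
            w_new = Xc.T @ yc
            w_new /= np.linalg.norm(w_new)
            delta = np.linalg.norm(w_new - w)
            w = w_new
            if delta <= tol:
                break
        else:
            raise ValueError(f"NIPALS did not converge for component {a + 1}")
        t = Xc @ w
        tt = float(t @ t)
        if tt <= DEGENERATE_SS:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        p_load = (Xc.T @ t) / tt
        q_a = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
    return PLSModel(x_mean, y_mean, W, P, q, T, x_scale=x_scale)


@dataclass
class CvReport:
    """Leave-one-out cross-validation summary over candidate depths 0..K.

    ``rmsep[k]`` is the LOO root-mean-squared prediction error of the
    k-component model (k = 0 is the mean-only model); ``press`` holds the
    per-subject squared errors behind it.  Variance accounting comes from the
    full-sample fit at depth K.
    """

    rmsep: np.ndarray  # (K+1,)
    press: np.ndarray  # (n, K+1) squared LOO errors
    x_variance_pct: np.ndarray  # (K+1,) cumulative % of X SS used
    y_variance_pct: np.ndarray  # (K+1,) cumulative % of y SS explained
    max_components: int
    selected: int | None = None


def loo_rmsep(X, y, max_components: int = 10, scale: bool = False) -> CvReport:
    """LOO-CV RMSEP for every candidate component count 0..max_components.

    Every left-out subject is predicted by a model refit from scratch on the
    remaining n-1 subjects; predictions at all cumulative depths come from a
    single K-component refit (NIPALS components are nested).
    """
    Xa = _as_array(X)
    ya = _as_array(y).ravel()
    n = Xa.shape[0]
    if n < max_components + 2:
        raise ValueError(f"need n >= max_components + 2 = {max_components + 2}, got {n}")
    K = max_components
    press = np.empty((n, K + 1))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xtr, ytr = Xa[keep], ya[keep]
        press[i, 0] = (ya[i] - ytr.mean()) ** 2
        if K == 0:
            continue
        try:
            model = nipals_fit(Xtr, ytr, K, scale=scale)
            path = model.predict_path(Xa[i : i + 1])[0]
        except ValueError:
            # rank (or X-y covariance) exhausted before K on this fold: carry
            # the deepest available prediction forward
            path = None
            for kk in range(min(K, int(np.linalg.matrix_rank(Xtr - Xtr.mean(axis=0)))), 0, -1):
                try:
                    model = nipals_fit(Xtr, ytr, kk, scale=scale)
                except ValueError:
                    continue
                part = model.predict_path(Xa[i : i + 1])[0]
                path = np.concatenate([part, np.repeat(part[-1], K - kk)])
                break
            if path is None:
                path = np.repeat(ytr.mean(), K)
        press[i, 1:] = (ya[i] - path) ** 2
    rmsep = np.sqrt(press.mean(axis=0))

    try:
        full = nipals_fit(Xa, ya, K, scale=scale)
        x_pct, y_pct = variance_accounting(full, Xa, ya)
    except ValueError:
        x_pct = y_pct = np.zeros(1)
        for kk in range(min(K, int(np.linalg.matrix_rank(Xa - Xa.mean(axis=0)))), 0, -1):
            try:
                full = nipals_fit(Xa, ya, kk, scale=scale)
            except ValueError:
                continue
            x_pct, y_pct = variance_accounting(full, Xa, ya)
            break
    pad = K + 1 - x_pct.shape[0]
    if pad > 0:
        x_pct = np.concatenate([x_pct, np.repeat(x_pct[-1], pad)])
        y_pct = np.concatenate([y_pct, np.repeat(y_pct[-1], pad)])
    return CvReport(rmsep, press, x_pct, y_pct, K)


def select_ncomponents(
    cv: CvReport,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    n_randomizations: int = 1999,
) -> int:
    """Pick the number of components by sign-randomization on paired LOO errors.

    Starting from the global-minimum-RMSEP depth, scan k = 0 upward and select
    the smallest k whose per-subject squared-error set is not significantly
    worse than the minimum's: the test statistic is the mean paired difference
    d_i = e2_{k,i} - e2_{min,i}, its null built by randomly flipping the signs
    of the d_i (one-sided, with the +1 correction).
    """
    if rng is None:
        rng = np.random.default_rng()
    k_min = int(np.argmin(cv.rmsep))
    n = cv.press.shape[0]
    for k in range(k_min + 1):
        if k == k_min:
            break
        d = cv.press[:, k] - cv.press[:, k_min]
        observed = d.mean()
        if observed <= 0:
            break
        signs = rng.integers(0, 2, size=(n_randomizations, n)) * 2.0 - 1.0
        null_means = signs @ d / n
        p = (1.0 + np.sum(null_means >= observed)) / (n_randomizations + 1.0)
        if p >= alpha:
            break
    cv.selected = k
    return k


def scrambled_null(
    X, y, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Null-model data: every predictor column's rows permuted independently
    and the response permuted, preserving all marginals."""
    Xa = _as_array(X)
    ya = _as_array(y).ravel()
    n, p = Xa.shape
    order = np.argsort(rng.random((n, p)), axis=0)
    return np.take_along_axis(Xa, order, axis=0), ya[rng.permutation(n)]


@dataclass
class SplitEnsemble:
    """Repeated random train/test splits with per-split fitted factors.

    ``loadings`` has shape (n_reps, p, k); ``test_r``/``test_rmsep`` hold the
    held-out correlation and RMSEP at every cumulative depth 1..k.
    """

    train_fraction: float
    n_components: int
    train_idx: list[np.ndarray]
    test_idx: list[np.ndarray]
    loadings: np.ndarray
    weights: np.ndarray
    y_loadings: np.ndarray
    test_r: np.ndarray
    test_rmsep: np.ndarray
    seed_sequence: list[int] = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return self.loadings.shape[0]


def split_sizes(n: int, train_fraction: float) -> tuple[int, int]:
    """Train/test sizes for a fraction split (train = floor(n * fraction))."""
    n_train = int(np.floor(n * train_fraction))
    return n_train, n - n_train


def repeated_splits(
    X,
    y,
    n_components: int,
    train_fraction: float = 0.8,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    scale: bool = False,
) -> SplitEnsemble:
    """Fit on random train fractions, evaluate on the held-out remainder.

    Supports the sensitivity fractions (0.9, 0.7, 0.6) as well as the default
    0.8.  Per-rep child seeds are derived deterministically from ``rng`` and
    recorded, so any single split is reproducible in isolation.
    """
    if not 0.5 < train_fraction < 0.95:
        raise ValueError(f"train_fraction must be in (0.5, 0.95), got {train_fraction}")
    if rng is None:
        rng = np.random.default_rng()
    Xa = _as_array(X)
    ya = _as_array(y).ravel()
    n, p = Xa.shape
    n_train, _ = split_sizes(n, train_fraction)
    child_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]

    train_idx, test_idx = [], []
    loadings = np.empty((n_reps, p, n_components))
    weights = np.empty((n_reps, p, n_components))
    y_loadings = np.empty((n_reps, n_components))
    test_r = np.empty((n_reps, n_components))
    test_rmsep = np.empty((n_reps, n_components))
    for rep, seed in enumerate(child_seeds):
        child = np.random.default_rng(seed)
        perm = child.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = nipals_fit(Xa[tr], ya[tr], n_components, scale=scale)
        path = model.predict_path(Xa[te])
        for a in range(n_components):
            resid = ya[te] - path[:, a]
            test_rmsep[rep, a] = np.sqrt(np.mean(resid**2))
            test_r[rep, a] = np.corrcoef(path[:, a], ya[te])[0, 1]
        train_idx.append(tr)
        test_idx.append(te)
        loadings[rep] = model.x_loadings
        weights[rep] = model.x_weights
        y_loadings[rep] = model.y_loadings
    return SplitEnsemble(
        train_fraction=train_fraction,
        n_components=n_components,
        train_idx=train_idx,
        test_idx=test_idx,
        loadings=loadings,
        weights=weights,
        y_loadings=y_loadings,
        test_r=test_r,
        test_rmsep=test_rmsep,
        seed_sequence=child_seeds,
    )


def variance_accounting(model: PLSModel, X, y) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (% X sum-of-squares used, % y variance explained) per depth.

    Depth 0 is included (both 0%).  X reconstruction uses the score/loading
    outer products; with orthogonal scores the captured SS telescopes to
    sum_a ||t_a||^2 ||p_a||^2.
    """
    Xa = _as_array(X)
    ya = _as_array(y).ravel()
    Xc = Xa - Xa.mean(axis=0)
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    yc = ya - ya.mean()
    ss_x = float(np.sum(Xc**2))
    ss_y = float(np.sum(yc**2))
    k = model.n_components
    x_pct = np.zeros(k + 1)
    y_pct = np.zeros(k + 1)
    yhat = np.zeros_like(yc)
    for a in range(k):
        t = model.scores[:, a]
        x_pct[a + 1] = x_pct[a] + 100.0 * float(t @ t) * float(
            model.x_loadings[:, a] @ model.x_loadings[:, a]
        ) / ss_x
        yhat = yhat + model.y_loadings[a] * t
        y_pct[a + 1] = 100.0 * (1.0 - float(np.sum((yc - yhat) ** 2)) / ss_y)
    return x_pct, y_pct
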