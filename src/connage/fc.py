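"""Functional connectivity construction from node-wise BOLD time series.

Pipeline per subject (node x time matrix, e.g. 296 retained volumes):

1. Pearson correlation between every pair of node time series -> symmetric
   r matrix.
2. Per-edge significance against phase-randomized surrogates: each node series
   is Fourier-transformed, its phases scrambled, and inverted, preserving the
   amplitude spectrum (hence autocorrelation) while destroying cross-series
   dependence.  The edge's null is the distribution of |r| between surrogate
   versions of its own two series; non-significant edges (p >= alpha) are set
   to zero.
3. Fisher r-to-z transform of the retained correlations.
4. Sign split into FC_pos (positive z) and FC_neg (absolute negative z), so
   that strength sums cannot cancel each other out.

The surrogate draws independent uniform phases per positive-frequency bin for
both series of an edge; DC and (for even length) Nyquist bins are untouched so
the surrogate stays real with the mean preserved.  The permutation p-value is
two-sided on |r| with the +1 correction, so p is never zero, and ties count
against significance.
"""

from __future__ import annotations

import numpy as np

from .matrices import ConnectivityMatrix

FISHER_CLIP = 1e-7


def pearson_fc(ts: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of node time series.

    Parameters
    ----------
    ts
        Node x time matrix; every row needs nonzero variance.

    Returns
    -------
    numpy.ndarray
        Symmetric correlation matrix with zero diagonal (self-edges are
        excluded throughout).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected node x time matrix, got shape {ts.shape}")
    if ts.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at node(s) {dead.tolist()}")
    r = np.corrcoef(ts)
    r = (r + r.T) / 2.0  # exact symmetry (corrcoef is symmetric only to rounding)
    np.fill_diagonal(r, 0.0)
    return np.clip(r, -1.0, 1.0)


def phase_surrogate(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate of one time series.

    Keeps the amplitude spectrum (and therefore mean, variance and
    autocorrelation) of the input while randomizing all phases except the DC
    bin and, for even length, the Nyquist bin.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("phase_surrogate expects a 1-D series")
    if series.size < 4:
        raise ValueError(f"need at least 4 time points, got {series.size}")
    return _phase_surrogate_rows(series[None, :], rng)[0]


def _phase_surrogate_rows(ts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent phase surrogates of every row of ``ts`` (vectorized)."""
    n, t = ts.shape
    spec = np.fft.rfft(ts, axis=1)
    shift = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=spec.shape))
    shift[:, 0] = 1.0  # DC: mean preserved
    if t % 2 == 0:
        shift[:, -1] = 1.0  # Nyquist bin must stay real
    return np.fft.irfft(spec * shift, n=t, axis=1)


def edge_significance(
    ts: np.ndarray,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation test of every edge's correlation against phase surrogates.

    For each of ``n_surrogates`` rounds, all node series are independently
    phase-scrambled and the full correlation matrix recomputed; the per-edge
    p-value is ``(1 + #{|r_surr| >= |r_obs|}) / (n_surrogates + 1)``.

    Returns
    -------
    (p_values, mask, masked_r)
        ``p_values``: symmetric matrix (diagonal 1); ``mask``: boolean matrix
        of retained edges (``p < alpha``); ``masked_r``: observed r with
        non-retained entries set to zero.
    """
    if n_surrogates < 19:
        raise ValueError(f"n_surrogates must be >= 19, got {n_surrogates}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be a probability, got {alpha}")
    if rng is None:
        rng = np.random.default_rng()
    ts = np.asarray(ts, dtype=float)
    r_obs = pearson_fc(ts)
    abs_obs = np.abs(r_obs)
    exceed = np.zeros_like(r_obs)
    for _ in range(n_surrogates):
        surr = _phase_surrogate_rows(ts, rng)
        r_surr = np.corrcoef(surr)
        np.fill_diagonal(r_surr, 0.0)
        exceed += np.abs(r_surr) >= abs_obs
    p = (1.0 + exceed) / (n_surrogates + 1.0)
    np.fill_diagonal(p, 1.0)
    mask = p < alpha
    return p, mask, np.where(mask, r_obs, 0.0)


def fisher_z(r: np.ndarray, clip: float | None = FISHER_CLIP) -> np.ndarray:
    """Fisher r-to-z transform, ``z = atanh(r)``; zeros stay zero.

    ``clip`` guards against degenerate finite-sample ``|r| = 1`` by clipping
    ``|r|`` to ``1 - clip`` first; pass ``clip=None`` to disable, in which
    case ``|r| = 1`` raises.
    """
    r = np.asarray(r, dtype=float)
    if clip is None:
        if np.any(np.abs(r) >= 1.0):
            raise ValueError("|r| = 1 encountered with clipping disabled")
        clipped = r
    else:
        clipped = np.clip(r, -1.0 + clip, 1.0 - clip)
    return np.arctanh(clipped)


def split_signed(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed z matrix into (positive part, absolute negative part).

    ``pos - neg`` reconstructs the input exactly.
    """
    z = np.asarray(z, dtype=float)
    return np.maximum(z, 0.0), np.maximum(-z, 0.0)


def build_fc(
    ts: np.ndarray,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix, np.ndarray]:
    """Full FC build: threshold, Fisher-transform and sign-split one subject.

    Returns ``(FCpos, FCneg, p_values)``.
    """
    p, _, masked_r = edge_significance(ts, n_surrogates=n_surrogates, alpha=alpha, rng=rng)
    z = fisher_z(masked_r)
    pos, neg = split_signed(z)
    meta = {"n_surrogates": n_surrogates, "alpha": alpha}
    return (
        ConnectivityMatrix(pos, "FCpos", meta=dict(meta)),
        ConnectivityMatrix(neg, "FCneg", meta=dict(meta)),
        p,
    )
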