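"""Structural connectivity: log transform of streamline-weight matrices.

SC weights arrive as symmetric non-negative streamline weight sums (SIFT-2
style, dimensionless); tractography itself is upstream of this package.  The
only processing step is a log10 compression of the heavy-tailed weights.  A
bare ``log10(w)`` is undefined at absent edges (w = 0) and negative for
w < 1, so the transform used is ``log10(offset + w)`` with ``offset = 1`` by
default: absent edges map to exactly 0 and the ordering of weights is kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix, check_symmetric


def sc_transform(
    weights: np.ndarray | ConnectivityMatrix, log_offset: float = 1.0
) -> ConnectivityMatrix:
    """Log-compress a streamline-weight matrix into an SC connectome.

    Nonzero weights ``w`` map to ``log10(log_offset + w)``; zero entries
    (absent edges) stay exactly zero.  Applying the transform to an
    already-transformed matrix is refused.
    """
    if isinstance(weights, ConnectivityMatrix):
        if weights.log_transformed:
            raise ValueError("matrix is already log-transformed; refusing to re-apply")
        w = weights.values
    else:
        w = np.asarray(weights, dtype=float)
    if log_offset <= 0:
        raise ValueError(f"log_offset must be positive, got {log_offset}")
    if np.any(w < 0):
        raise ValueError("streamline weights must be non-negative")
    check_symmetric(w)
    out = np.where(w > 0, np.log10(log_offset + w), 0.0)
    return ConnectivityMatrix(out, "SC", log_transformed=True, meta={"log_offset": log_offset})


def triangularize(m: ConnectivityMatrix | np.ndarray) -> pd.DataFrame:
    """Upper-triangle edge list (i < j, weight) of a symmetric matrix.

    Only unidirectional edge information is used downstream; the diagonal is
    excluded.  Exactly N(N-1)/2 rows are returned.
    """
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    check_symmetric(values)
    i, j = np.triu_indices(values.shape[0], k=1)
    return pd.DataFrame({"i": i, "j": j, "weight": values[i, j]})


def edges_to_matrix(edges: pd.DataFrame, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix from a triangular edge list (zero diagonal)."""
    out = np.zeros((n_nodes, n_nodes))
    i = edges["i"].to_numpy(dtype=int)
    j = edges["j"].to_numpy(dtype=int)
    if np.any(i >= j):
        raise ValueError("edge list must have i < j")
    out[i, j] = edges["weight"].to_numpy(dtype=float)
    out[j, i] = out[i, j]
    return out
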