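"""Node-wise intra-/inter-network strength features and the predictor block.

Each subject's three connectomes (SC, FC_pos, FC_neg) are reduced to two
strength estimates per node:

* intra-network: sum of the node's edge weights to nodes of its own network,
  divided by the number of possible edges in that network, n(n-1)/2 for a
  network of n nodes (a network-level denominator, applied as written in the
  source procedure even though the numerator is per-node);
* inter-network: sum of the node's edge weights to out-of-network nodes,
  divided by the number of such possible edges.  The denominator is per-node
  (N - n) by default; the alternative reading (network total n*(N - n)) is
  available via ``inter_denominator="network-total"``.

For N nodes this yields 6N connectivity predictors per subject (N x 6 strength
values: 2400 at the reference 400-node resolution), to which the cognition
composite COG is appended as the final predictor column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix
from .parcellation import validate_parcellation

#: Predictor family order within each node's block of columns.
FAMILIES: tuple[tuple[str, str], ...] = (
    ("SC", "intra"),
    ("SC", "inter"),
    ("FCpos", "intra"),
    ("FCpos", "inter"),
    ("FCneg", "intra"),
    ("FCneg", "inter"),
)

COG_COLUMN = "COG"

INTER_DENOMINATORS = ("per-node", "network-total")


@dataclass
class FeatureBlock:
    """Subjects x predictors block plus per-predictor tags.

    ``data`` columns follow the documented ordering: for node 0..N-1 the six
    family columns in :data:`FAMILIES` order, then ``COG`` if present.
    ``tags`` is indexed by predictor name with columns
    ``kind, scope, node, network, lobe`` (NA for the COG column).
    """

    data: pd.DataFrame
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.tags.index):
            raise ValueError("tags index must match data columns exactly")
        if self.data.isna().any().any():
            raise ValueError("feature block contains missing values")

    @property
    def has_cog(self) -> bool:
        return COG_COLUMN in self.data.columns

    @property
    def n_predictors(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def predictor_name(node: int, kind: str, scope: str) -> str:
    return f"n{node:04d}_{kind}_{scope}"


def feature_columns(n_nodes: int, with_cog: bool = True) -> list[str]:
    """Canonical predictor column names for an N-node parcellation."""
    cols = [
        predictor_name(node, kind, scope)
        for node in range(n_nodes)
        for kind, scope in FAMILIES
    ]
    if with_cog:
        cols.append(COG_COLUMN)
    return cols


def _network_geometry(parc: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-node network size and a node x network membership indicator."""
    networks = parc["network"].to_numpy()
    uniq = pd.unique(networks)
    membership = np.stack([networks == net for net in uniq], axis=1).astype(float)
    sizes = membership.sum(axis=0)  # nodes per network
    node_net_size = membership @ sizes
    return node_net_size, membership


def node_strengths(
    m: ConnectivityMatrix,
    parc: pd.DataFrame,
    inter_denominator: str = "per-node",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized intra- and inter-network strength for every node.

    Returns ``(intra, inter)`` arrays of length N.
    """
    if inter_denominator not in INTER_DENOMINATORS:
        raise ValueError(f"inter_denominator must be one of {INTER_DENOMINATORS}")
    validate_parcellation(parc)
    v = m.values
    n_total = v.shape[0]
    if n_total != len(parc):
        raise ValueError(f"matrix has {n_total} nodes but parcellation has {len(parc)}")
    node_net_size, membership = _network_geometry(parc)
    if np.any(node_net_size < 2):
        bad = np.flatnonzero(node_net_size < 2)
        raise ValueError(f"singleton network for node(s) {bad.tolist()}")

    per_network_sums = v @ membership  # (N, n_networks): weight to each network
    intra_sum = np.einsum("ij,ij->i", per_network_sums, membership)
    inter_sum = v.sum(axis=1) - intra_sum

    intra = intra_sum / (node_net_size * (node_net_size - 1) / 2.0)
    if inter_denominator == "per-node":
        inter_den = n_total - node_net_size
    else:
        inter_den = node_net_size * (n_total - node_net_size)
    inter = np.where(inter_den > 0, inter_sum / np.where(inter_den > 0, inter_den, 1.0), 0.0)
    return intra, inter


def intra_strength(m: ConnectivityMatrix, parc: pd.DataFrame, node: int) -> float:
    """Intra-network strength of one node (see module docstring for the formula)."""
    intra, _ = node_strengths(m, parc)
    return float(intra[node])


def inter_strength(
    m: ConnectivityMatrix,
    parc: pd.DataFrame,
    node: int,
    inter_denominator: str = "per-node",
) -> float:
    """Inter-network strength of one node."""
    _, inter = node_strengths(m, parc, inter_denominator=inter_denominator)
    return float(inter[node])


def subject_features(
    matrices: dict[str, ConnectivityMatrix],
    parc: pd.DataFrame,
    inter_denominator: str = "per-node",
) -> np.ndarray:
    """One subject's 6N strength vector in canonical column order."""
    strengths = {}
    for kind in ("SC", "FCpos", "FCneg"):
        if kind not in matrices:
            raise ValueError(f"missing {kind} matrix")
        if matrices[kind].kind != kind:
            raise ValueError(f"matrix tagged {matrices[kind].kind!r} supplied as {kind!r}")
        strengths[kind] = node_strengths(matrices[kind], parc, inter_denominator)
    n_nodes = len(parc)
    out = np.empty(6 * n_nodes)
    for f_idx, (kind, scope) in enumerate(FAMILIES):
        col = strengths[kind][0 if scope == "intra" else 1]
        out[f_idx::6] = col
    return out


def predictor_tags(parc: pd.DataFrame, with_cog: bool = True) -> pd.DataFrame:
    """Per-predictor (kind, scope, node, network, lobe) tag table."""
    n_nodes = len(parc)
    rows = []
    for node in range(n_nodes):
        net = parc.at[node, "network"]
        lobe = parc.at[node, "lobe"]
        for kind, scope in FAMILIES:
            rows.append(
                {
                    "predictor": predictor_name(node, kind, scope),
                    "kind": kind,
                    "scope": scope,
                    "node": node,
                    "network": net,
                    "lobe": lobe,
                }
            )
    if with_cog:
        rows.append(
            {
                "predictor": COG_COLUMN,
                "kind": "COG",
                "scope": pd.NA,
                "node": pd.NA,
                "network": pd.NA,
                "lobe": pd.NA,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def assemble_features(
    subject_matrices: dict[str, dict[str, ConnectivityMatrix]],
    parc: pd.DataFrame,
    cog: pd.Series | None = None,
    inter_denominator: str = "per-node",
) -> FeatureBlock:
    """Assemble the subjects x (6N [+ COG]) predictor block.

    Parameters
    ----------
    subject_matrices
        Mapping subject id -> {"SC": ..., "FCpos": ..., "FCneg": ...}.
    cog
        Optional per-subject cognition composite, indexed by subject id; must
        cover every subject when given.
    """
    subjects = list(subject_matrices)
    if cog is not None:
        missing = [s for s in subjects if s not in cog.index or pd.isna(cog.loc[s])]
        if missing:
            raise ValueError(f"COG missing for subject(s) {missing}")
    rows = []
    for sid in subjects:
        try:
            rows.append(subject_features(subject_matrices[sid], parc, inter_denominator))
        except ValueError as exc:
            raise ValueError(f"subject {sid!r}: {exc}") from exc
    data = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index(subjects, name="subject_id"),
        columns=feature_columns(len(parc), with_cog=False),
    )
    if cog is not None:
        data[COG_COLUMN] = cog.loc[subjects].to_numpy(dtype=float)
    return FeatureBlock(data, predictor_tags(parc, with_cog=cog is not None))
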