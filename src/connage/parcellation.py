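"""Cortical parcellation lookup: node -> resting-state network, lobe, hemisphere.

The analysis operates on a fixed division of cortex into labelled nodes, each
assigned to one of the seven canonical resting-state networks (visual VN,
sensorimotor SMN, limbic LN, frontoparietal FPN, default mode DMN, dorsal
attention DAN, ventral attention VAN) and to a coarse lobe label
(frontal / other).  The lookup defines the intra-/inter-network edge sets used
by the strength features and the frontal-vs-rest contrast on loadings.

The default scheme has 400 nodes (the resolution used for the reference
analysis); tests use 100.  Assignment is fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical seven resting-state networks, in fixed order.
NETWORKS: tuple[str, ...] = ("VN", "SMN", "LN", "FPN", "DMN", "DAN", "VAN")

LOBES: tuple[str, str] = ("frontal", "other")
HEMISPHERES: tuple[str, str] = ("left", "right")

PARCELLATION_COLUMNS = ["node_id", "network", "lobe", "hemisphere"]


def default_network_sizes(n_nodes: int) -> dict[str, int]:
    """Split ``n_nodes`` across the seven networks as evenly as possible.

    The first ``n_nodes % 7`` networks (in :data:`NETWORKS` order) receive one
    extra node.
    """
    base, extra = divmod(n_nodes, len(NETWORKS))
    return {net: base + (1 if i < extra else 0) for i, net in enumerate(NETWORKS)}


def make_parcellation(
    n_nodes: int = 400,
    network_sizes: dict[str, int] | None = None,
    frontal_fraction: float = 0.3,
) -> pd.DataFrame:
    """Build a deterministic node -> (network, lobe, hemisphere) lookup.

    Parameters
    ----------
    n_nodes
        Total number of nodes; must be at least 14 (two per network).
    network_sizes
        Optional node count per network name; must cover exactly the seven
        canonical networks and sum to ``n_nodes``, each at least 2.
    frontal_fraction
        Approximate proportion of each network's nodes labelled ``frontal``.
        Within every network the first ``round(frontal_fraction * size)`` nodes
        (clipped so no network is all-frontal when size permits) get the
        frontal label, so networks span both lobes — as the frontoparietal,
        sensorimotor, default-mode and ventral-attention networks do in the
        reference scheme.

    Returns
    -------
    pandas.DataFrame
        Columns ``node_id`` (0..N-1), ``network``, ``lobe``, ``hemisphere``.
    """
    if n_nodes < 14:
        raise ValueError(f"n_nodes must be >= 14 (two per network), got {n_nodes}")
    if not 0.0 <= frontal_fraction <= 1.0:
        raise ValueError(f"frontal_fraction must be in [0, 1], got {frontal_fraction}")
    if network_sizes is None:
        network_sizes = default_network_sizes(n_nodes)
    if set(network_sizes) != set(NETWORKS):
        raise ValueError(
            f"network_sizes keys must be exactly {set(NETWORKS)}, got {set(network_sizes)}"
        )
    total = sum(network_sizes.values())
    if total != n_nodes:
        raise ValueError(f"network_sizes sum to {total}, expected n_nodes={n_nodes}")
    for net, size in network_sizes.items():
        if size < 2:
            raise ValueError(f"network {net!r} has size {size}; every network needs >= 2 nodes")

    records = []
    node_id = 0
    for net in NETWORKS:
        size = network_sizes[net]
        n_frontal = int(round(frontal_fraction * size))
        if frontal_fraction < 1.0:
            n_frontal = min(n_frontal, size - 1)  # keep both lobes represented
        if frontal_fraction > 0.0:
            n_frontal = max(n_frontal, 1)
        for k in range(size):
            records.append(
                {
                    "node_id": node_id,
                    "network": net,
                    "lobe": "frontal" if k < n_frontal else "other",
                    "hemisphere": HEMISPHERES[node_id % 2],
                }
            )
            node_id += 1
    parc = pd.DataFrame.from_records(records, columns=PARCELLATION_COLUMNS)
    return parc


def validate_parcellation(parc: pd.DataFrame) -> None:
    """Raise ``ValueError`` if ``parc`` violates the lookup invariants."""
    missing = set(PARCELLATION_COLUMNS) - set(parc.columns)
    if missing:
        raise ValueError(f"parcellation missing columns: {sorted(missing)}")
    n = len(parc)
    if not np.array_equal(parc["node_id"].to_numpy(), np.arange(n)):
        raise ValueError("node_id must be 0..N-1 in order")
    if not set(parc["network"]).issubset(NETWORKS):
        raise ValueError(f"unknown networks: {set(parc['network']) - set(NETWORKS)}")
    if not set(parc["lobe"]).issubset(LOBES):
        raise ValueError(f"unknown lobes: {set(parc['lobe']) - set(LOBES)}")
    counts = parc["network"].value_counts()
    empty = [net for net in NETWORKS if counts.get(net, 0) == 0]
    if empty:
        raise ValueError(f"empty networks: {empty}")


def network_nodes(parc: pd.DataFrame) -> dict[str, np.ndarray]:
    """Node index arrays per network."""
    return {
        net: parc.loc[parc["network"] == net, "node_id"].to_numpy()
        for net in NETWORKS
        if (parc["network"] == net).any()
    }
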