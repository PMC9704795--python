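"""Connectivity matrix container shared by the FC and SC builders."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed connectome kinds: structural, positive functional, negative functional.
KINDS = ("SC", "FCpos", "FCneg")

SYMMETRY_TOL = 1e-9


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node edge-weight matrix with a kind tag.

    Only the upper triangle carries information (edges are undirected); the
    diagonal is excluded from every downstream computation and kept at zero.
    ``log_transformed`` marks SC matrices that already went through the log
    transform so it cannot be applied twice.
    """

    values: np.ndarray
    kind: str
    log_transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"values must be square, got shape {self.values.shape}")
        check_symmetric(self.values)
        if self.kind in ("FCpos", "FCneg") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} entries must be non-negative")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def check_symmetric(values: np.ndarray, tol: float = SYMMETRY_TOL) -> None:
    """Raise ``ValueError`` if ``values`` is asymmetric beyond ``tol``."""
    dev = np.max(np.abs(values - values.T)) if values.size else 0.0
    if dev > tol:
        raise ValueError(f"matrix asymmetric: max |A - A.T| = {dev:.3g} > {tol:g}")
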