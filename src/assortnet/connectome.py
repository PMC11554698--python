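"""Connectome container and adjacency-matrix I/O.

A connectome is one subject's weighted undirected brain network over a fixed
parcellation: a square symmetric adjacency matrix tagged as structural (edge
weights are fiber counts, non-negative) or functional (edge weights are
partial correlations, possibly negative), optionally carrying a node-label
table in the style of the Schaefer 400-parcel atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import InvalidParameterError

SYMMETRY_TOL = 1e-10

#: Canonical cortical functional systems used for synthetic node labels.
CANONICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "SalienceVentralAttention",
    "Limbic",
    "Control",
    "DefaultMode",
)


@dataclass
class Connectome:
    """Weighted undirected network for one subject.

    Parameters
    ----------
    adjacency:
        Square symmetric matrix of edge weights; zero means no edge and the
        diagonal is zero.
    modality:
        ``"structural"`` (non-negative fiber-count weights) or
        ``"functional"`` (signed partial-correlation weights).
    node_labels:
        Optional table with columns ``node_id``, ``hemisphere``, ``network``,
        ``region``.
    """

    adjacency: np.ndarray
    modality: str = "structural"
    node_labels: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidParameterError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] < 2:
            raise InvalidParameterError("a connectome needs at least 2 nodes")
        if not np.all(np.isfinite(A)):
            raise InvalidParameterError("adjacency contains non-finite values")
        if np.abs(A - A.T).max() > SYMMETRY_TOL:
            raise InvalidParameterError("adjacency is not symmetric within 1e-10")
        if np.abs(np.diagonal(A)).max() > 0:
            raise InvalidParameterError("adjacency diagonal must be zero (no self-loops)")
        if self.modality not in ("structural", "functional"):
            raise InvalidParameterError(f"unknown modality {self.modality!r}")
        if self.modality == "structural" and A.min() < 0:
            raise InvalidParameterError("structural weights (fiber counts) must be >= 0")
        # store a symmetrized copy so downstream algebra is exactly symmetric
        self.adjacency = (A + A.T) / 2.0
        np.fill_diagonal(self.adjacency, 0.0)

    @property
    def node_count(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.node_count, k=1)
        return int(np.count_nonzero(self.adjacency[iu]))


def read_adjacency(path: str | Path) -> np.ndarray:
    """Read a square adjacency matrix from CSV (headerless) or MatrixMarket."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        M = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return np.asarray(M, dtype=float)
    return np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)


def write_adjacency(A: np.ndarray, path: str | Path) -> None:
    """Write a square adjacency matrix; format chosen from the extension.

    CSV uses ``%.17g`` so values round-trip exactly in double precision;
    MTX is written as a symmetric sparse coordinate matrix.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        # symmetric coordinate format stores the lower triangle
        S = scipy.sparse.coo_matrix(np.tril(A))
        scipy.io.mmwrite(str(path), S, symmetry="symmetric", precision=17)
    else:
        np.savetxt(path, np.asarray(A, dtype=float), delimiter=",", fmt="%.17g")


def read_node_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"node_id": int})
    required = ["node_id", "hemisphere", "network", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"node-label table missing columns: {missing}")
    return df[required]


def write_node_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def make_node_labels(node_count: int) -> pd.DataFrame:
    """Synthetic Schaefer-style label table: L/R split, 7 canonical systems."""
    half = node_count // 2
    rows = []
    for i in range(node_count):
        hemi = "L" if i < half else "R"
        net = CANONICAL_NETWORKS[i % len(CANONICAL_NETWORKS)]
        idx = i if i < half else i - half
        rows.append((i, hemi, net, f"{hemi}_{net}_{idx}"))
    return pd.DataFrame(rows, columns=["node_id", "hemisphere", "network", "region"])
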