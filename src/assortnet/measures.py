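"""Global and nodal graph measures for weighted brain networks.

The centerpiece is the nodal (local) assortativity decomposition: global
assortativity r is the Pearson correlation between the degrees of connected
node pairs, and it admits an exact per-node decomposition through the
normalized neighbor-degree disparity,

    delta_i    = (1/d_i) * sum_{j in N_i} |d_j - d_i|
    deltabar_i = delta_i / sum_j delta_j
    r_i        = (r + 1)/m - deltabar_i

with m the number of nodes, so that sum_i deltabar_i = 1 and sum_i r_i = r.
A node whose neighbors have degrees very unlike its own (large disparity)
carries a low, possibly negative, r_i.

Degrees default to binary degrees on the network binarized at |weight| > 0
("number of neighbors"); a weighted mode substitutes node strengths for
degrees. Clustering coefficient and betweenness centrality are delegated to
networkx (Onnela geometric-mean triangle weights; Brandes shortest-path
counting with length 1/|weight| in weighted mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import Connectome
from .exceptions import InvalidParameterError, NoEdgesError

__all__ = [
    "NodalMeasureVector",
    "binarize",
    "global_assortativity",
    "nodal_assortativity",
    "clustering_coefficient",
    "betweenness_centrality",
    "node_strength",
    "node_degree",
    "compute_measure",
    "MEASURES",
]

MEASURES = ("NA", "CC", "BC", "NS", "ND")


@dataclass
class NodalMeasureVector:
    """Per-node values of one local measure on one network."""

    measure: str
    values: np.ndarray
    degree_mode: str = "binary"
    #: True when the measure hit a degenerate case (e.g. nodal assortativity
    #: on a regular graph, where r is undefined).
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def _check_degree_mode(degree_mode: str) -> None:
    if degree_mode not in ("binary", "weighted"):
        raise InvalidParameterError(f"degree_mode must be binary|weighted, got {degree_mode!r}")


def binarize(net: Connectome, threshold: float = 0.0) -> Connectome:
    """Indicator network: edge where ``|weight| > threshold``.

    Negative functional weights count by magnitude — a strong negative
    partial correlation is still a connection.
    """
    if threshold < 0:
        raise InvalidParameterError("threshold must be >= 0")
    B = (np.abs(net.adjacency) > threshold).astype(float)
    np.fill_diagonal(B, 0.0)
    return Connectome(B, modality=net.modality, node_labels=net.node_labels)


def _degrees(net: Connectome, degree_mode: str) -> np.ndarray:
    _check_degree_mode(degree_mode)
    if degree_mode == "binary":
        return (np.abs(net.adjacency) > 0).sum(axis=1).astype(float)
    return np.abs(net.adjacency).sum(axis=1)


def _directed_degree_pairs(net: Connectome, degree_mode: str):
    """Endpoint degrees over the directed edge list (both orientations)."""
    d = _degrees(net, degree_mode)
    ii, jj = np.nonzero(np.triu(np.abs(net.adjacency) > 0, k=1))
    if ii.size == 0:
        raise NoEdgesError("network has no edges")
    x = np.concatenate([d[ii], d[jj]])
    y = np.concatenate([d[jj], d[ii]])
    return x, y


def global_assortativity(net: Connectome, degree_mode: str = "binary") -> float:
    """Degree assortativity r: Pearson correlation of endpoint degrees.

    Each undirected edge contributes both orientations, the standard
    estimator for undirected networks. Returns NaN when every connected node
    has the same degree (zero variance, correlation undefined). Raises
    :class:`NoEdgesError` on an edgeless network.
    """
    x, y = _directed_degree_pairs(net, degree_mode)
    vx = x.var()
    if vx == 0:
        return float("nan")
    # x and y are permutations of each other, so var(x) == var(y)
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def nodal_assortativity(net: Connectome, degree_mode: str = "binary") -> NodalMeasureVector:
    """Per-node decomposition of global assortativity.

    Returns r_i = (r+1)/m - deltabar_i; the vector sums exactly to r. An
    isolated node has empty neighbor disparity (delta_i = 0) but stays in the
    vector so its length always equals the atlas size. On a regular graph
    (all disparities zero) r is undefined: deltabar_i is set uniformly to 1/m
    to preserve its unit sum and the r_i are flagged degenerate (NaN).
    """
    d = _degrees(net, degree_mode)
    B = (np.abs(net.adjacency) > 0).astype(float)
    if not B.any():
        raise NoEdgesError("network has no edges")
    m = net.node_count
    # delta_i = (1/d_i) sum_j B_ij |d_j - d_i|; 0 for isolated nodes
    disparity = np.abs(d[None, :] - d[:, None])
    delta = np.where(d > 0, (B * disparity).sum(axis=1) / np.where(d > 0, d, 1.0), 0.0)
    total = delta.sum()
    if total == 0:  # regular among connected nodes: r undefined
        deltabar = np.full(m, 1.0 / m)
        r_i = np.full(m, np.nan)
        return NodalMeasureVector(
            "NA", r_i, degree_mode, degenerate=True,
            extras={"delta": delta, "deltabar": deltabar, "r": float("nan")},
        )
    deltabar = delta / total
    r = global_assortativity(net, degree_mode)
    r_i = (r + 1.0) / m - deltabar
    return NodalMeasureVector(
        "NA", r_i, degree_mode,
        extras={"delta": delta, "deltabar": deltabar, "r": r},
    )


def _as_graph(net: Connectome, weight: str | None) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.node_count))
    ii, jj = np.nonzero(np.triu(np.abs(net.adjacency) > 0, k=1))
    if weight is None:
        G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    else:
        w = np.abs(net.adjacency[ii, jj])
        if weight == "length":
            w = 1.0 / w
        G.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), w.tolist()), weight=weight)
    return G


def clustering_coefficient(net: Connectome, degree_mode: str = "binary") -> NodalMeasureVector:
    """Per-node triangle density 2t_i/(d_i(d_i-1)); 0 when d_i < 2.

    Weighted mode uses the geometric-mean-of-weights triangle variant on
    |weights| rescaled to [0, 1] by the maximum magnitude.
    """
    _check_degree_mode(degree_mode)
    if degree_mode == "binary":
        cc = nx.clustering(_as_graph(net, None))
    else:
        cc = nx.clustering(_as_graph(net, "weight"), weight="weight")
    vals = np.array([cc[i] for i in range(net.node_count)], dtype=float)
    return NodalMeasureVector("CC", vals, degree_mode)


def betweenness_centrality(net: Connectome, degree_mode: str = "binary") -> NodalMeasureVector:
    """Unnormalized shortest-path betweenness over unordered source-target pairs.

    Binary mode treats every edge as unit length; weighted mode uses length
    1/|weight| so strong connections are short. Disconnected pairs contribute
    nothing.
    """
    _check_degree_mode(degree_mode)
    if degree_mode == "binary":
        bc = nx.betweenness_centrality(_as_graph(net, None), normalized=False)
    else:
        bc = nx.betweenness_centrality(_as_graph(net, "length"), weight="length", normalized=False)
    vals = np.array([bc[i] for i in range(net.node_count)], dtype=float)
    return NodalMeasureVector("BC", vals, degree_mode)


def node_strength(net: Connectome) -> NodalMeasureVector:
    """Row sums of |weights| (magnitude encodes connection presence)."""
    return NodalMeasureVector("NS", np.abs(net.adjacency).sum(axis=1), "weighted")


def node_degree(net: Connectome, threshold: float = 0.0) -> NodalMeasureVector:
    """Number of neighbors after binarizing at |weight| > threshold."""
    B = binarize(net, threshold)
    return NodalMeasureVector("ND", B.adjacency.sum(axis=1), "binary")


def compute_measure(net: Connectome, measure: str, degree_mode: str = "binary") -> NodalMeasureVector:
    """Dispatch by measure code (NA, CC, BC, NS, ND)."""
    if measure == "NA":
        return nodal_assortativity(net, degree_mode)
    if measure == "CC":
        return clustering_coefficient(net, degree_mode)
    if measure == "BC":
        return betweenness_centrality(net, degree_mode)
    if measure == "NS":
        return node_strength(net)
    if measure == "ND":
        return node_degree(net)
    raise InvalidParameterError(f"unknown measure {measure!r}; expected one of {MEASURES}")
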