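"""Topological and weight features of a candidate complex subgraph.

A candidate complex is described by an 11-component vector computed on the
subgraph it induces in the unweighted network plus the same subgraph of the
GO-weighted network:

    density,
    degree_mean, degree_max, degree_min, degree_var,
    weight_sum, weight_mean, weight_max, weight_min,
    clustering_coeff,
    topologic_change

Degrees are induced-subgraph degrees: the features describe the candidate
itself, not its embedding. Variance is the population variance (defined for
any group size). The topologic-change feature is the drop in density when
the highest-degree member is removed — how much the densest hub holds the
subgraph together.

The component order is frozen in :data:`FEATURE_NAMES`; a trained model
records the registry it was fit against and scoring with a mismatched
registry is rejected.
"""

from __future__ import annotations

import numpy as np

from .network_io import PPINetwork

__all__ = [
    "FEATURE_NAMES",
    "graph_density",
    "clustering_coefficient",
    "degree_statistics",
    "edge_weight_statistics",
    "topologic_change",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    "density",
    "degree_mean",
    "degree_max",
    "degree_min",
    "degree_var",
    "weight_sum",
    "weight_mean",
    "weight_max",
    "weight_min",
    "clustering_coeff",
    "topologic_change",
)


def _require_group(members) -> frozenset:
    members = frozenset(members)
    if len(members) < 2:
        raise ValueError("feature computation requires at least 2 members")
    return members


def _induced_neighbors(members: frozenset, net: PPINetwork) -> dict:
    """Member -> set of its neighbors inside the group.

    Works on the backing adjacency directly; building networkx subgraph
    views per candidate is far too slow for the greedy growth loop.
    """
    adj = net.graph.adj
    return {
        v: ({u for u in adj[v] if u in members} if v in adj else set())
        for v in members
    }


def _density_from(nbrs: dict) -> float:
    k = len(nbrs)
    e2 = sum(len(s) for s in nbrs.values())  # 2e
    return e2 / (k * (k - 1))


def graph_density(members, net: PPINetwork) -> float:
    """2e / (k(k-1)) over the induced subgraph; 1 for a clique, 0 edgeless."""
    members = _require_group(members)
    return _density_from(_induced_neighbors(members, net))


def clustering_coefficient(members, net: PPINetwork) -> float:
    """Mean local clustering coefficient within the induced subgraph.

    Each member with induced degree >= 2 contributes the fraction of its
    neighbor pairs that are themselves connected; degree-0/1 members
    contribute 0.
    """
    members = _require_group(members)
    nbrs = _induced_neighbors(members, net)
    total = 0.0
    for v, nv in nbrs.items():
        k = len(nv)
        if k < 2:
            continue
        links2 = sum(len(nbrs[u] & nv) for u in nv)  # each link counted twice
        total += links2 / (k * (k - 1))
    return total / len(members)


def degree_statistics(members, net: PPINetwork) -> tuple[float, float, float, float]:
    """(mean, max, min, population variance) of induced-subgraph degrees."""
    members = _require_group(members)
    nbrs = _induced_neighbors(members, net)
    degs = np.fromiter((len(s) for s in nbrs.values()), float, len(nbrs))
    return (float(degs.mean()), float(degs.max()), float(degs.min()), float(degs.var()))


def edge_weight_statistics(members, wnet: PPINetwork) -> tuple[float, float, float, float]:
    """(sum, mean, max, min) of internal edge weights; all 0 with no internal edges."""
    members = _require_group(members)
    if not wnet.weighted:
        raise ValueError("edge-weight statistics require a weighted network")
    adj = wnet.graph.adj
    ws = [
        d["weight"]
        for v in members
        if v in adj
        for u, d in adj[v].items()
        if u in members and u > v
    ]
    if not ws:
        return (0.0, 0.0, 0.0, 0.0)
    arr = np.array(ws, float)
    return (float(arr.sum()), float(arr.mean()), float(arr.max()), float(arr.min()))


def topologic_change(members, net: PPINetwork) -> float:
    """Density drop when the best-connected member is removed.

    The removed node is the member with the highest induced degree
    (smallest ID on ties). Groups smaller than 3 return 0 by convention
    (removing a node would leave fewer than 2 members).
    """
    members = frozenset(members)
    if len(members) < 3:
        return 0.0
    nbrs = _induced_neighbors(members, net)
    hub = min(sorted(members), key=lambda v: -len(nbrs[v]))
    rest = {v: s - {hub} for v, s in nbrs.items() if v != hub}
    return _density_from(nbrs) - _density_from(rest)


def extract_features(members, net: PPINetwork, wnet: PPINetwork) -> np.ndarray:
    """Assemble the 11-component feature vector in :data:`FEATURE_NAMES` order."""
    members = _require_group(members)
    d_mean, d_max, d_min, d_var = degree_statistics(members, net)
    w_sum, w_mean, w_max, w_min = edge_weight_statistics(members, wnet)
    return np.array(
        [
            graph_density(members, net),
            d_mean,
            d_max,
            d_min,
            d_var,
            w_sum,
            w_mean,
            w_max,
            w_min,
            clustering_coefficient(members, net),
            topologic_change(members, net),
        ],
        dtype=float,
    )
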