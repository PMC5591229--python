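"""Global and local statistics of the weighted plants/VOC graphs.

Density D = 2E / (N(N−1)), mean degree k̄ = 2E/V, per-node degree k_i and
strength s_i = Σ_j a_ij w_ij, the Barrat weighted clustering coefficient

    c_i^w = 1/(s_i (k_i − 1)) Σ_{jh} (w_ij + w_ih)/2 · a_ij a_ih a_jh,

and complementary cumulative distributions (CCDF) of degree and strength.
Isolated nodes have k = s = 0 by definition and an undefined clustering
coefficient; density can be reported with or without them since removing
the non-emitting species changes the picture substantially.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "density",
    "degree_and_strength",
    "weighted_clustering",
    "ccdf",
    "isolated_nodes",
    "MetricsReport",
    "metrics_report",
]


def isolated_nodes(g: nx.Graph) -> set:
    """Nodes with degree 0 (species sharing no above-threshold VOC)."""
    return {n for n in g if g.degree(n) == 0}


def density(g: nx.Graph, include_isolated: bool = True) -> float:
    """Edge density 2E / (N(N−1)) on the chosen node set."""
    n = g.number_of_nodes()
    if not include_isolated:
        n -= len(isolated_nodes(g))
    if n < 2:
        raise ValueError("density needs at least 2 nodes after isolated-node removal")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def degree_and_strength(g: nx.Graph) -> tuple[dict, dict]:
    """Neighbor count k_i and incident-weight sum s_i per node."""
    k = {n: g.degree(n) for n in g}
    s = {n: float(g.degree(n, weight="weight")) for n in g}
    return k, s


def weighted_clustering(g: nx.Graph, node=None):
    """Barrat weighted clustering coefficient; NaN where k_i < 2.

    Combines topology with the weight distribution: each closed triple at
    i contributes the mean weight of the two edges anchored at i,
    normalized by s_i (k_i − 1) so the value lies in [0, 1].  Undefined
    (NaN) for nodes with fewer than two neighbors; report tooling excludes
    those entries.
    """
    if node is not None:
        return _barrat(g, node)
    return {n: _barrat(g, n) for n in g}


def _barrat(g: nx.Graph, i) -> float:
    nbrs = list(g[i])
    k = len(nbrs)
    if k < 2:
        return math.nan
    s = g.degree(i, weight="weight")
    total = 0.0
    for a in range(k):
        j = nbrs[a]
        wij = g[i][j].get("weight", 1)
        for b in range(a + 1, k):
            h = nbrs[b]
            if g.has_edge(j, h):
                wih = g[i][h].get("weight", 1)
                total += (wij + wih) / 2.0
    # Σ over ordered pairs (j,h) is twice the unordered sum
    return 2.0 * total / (s * (k - 1))


def ccdf(values) -> list[tuple[float, float]]:
    """Empirical P(X > x) evaluated at each distinct value, nonincreasing."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("ccdf of an empty sample is undefined")
    xs = np.unique(x)
    n = x.size
    return [(float(v), float((x > v).sum()) / n) for v in xs]


@dataclass
class MetricsReport:
    n_nodes: int
    n_edges: int
    density_all: float | None
    density_active: float | None
    mean_degree: float
    degree: dict
    strength: dict
    clustering: dict
    degree_ccdf: list = field(default_factory=list)
    strength_ccdf: list = field(default_factory=list)
    isolated: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")


def metrics_report(g: nx.Graph) -> MetricsReport:
    """Full basic-metrics summary of a weighted graph.

    CCDFs (and the clustering table's defined entries) are computed over
    non-isolated nodes, since degree and strength of an isolated node are
    0 by definition and its clustering coefficient is undefined.
    """
    k, s = degree_and_strength(g)
    iso = sorted(isolated_nodes(g))
    active = [n for n in g if n not in set(iso)]
    cw = weighted_clustering(g)
    n = g.number_of_nodes()
    return MetricsReport(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        density_all=density(g, include_isolated=True) if n >= 2 else None,
        density_active=(
            density(g, include_isolated=False) if n - len(iso) >= 2 else None
        ),
        mean_degree=2.0 * g.number_of_edges() / n if n else 0.0,
        degree=k,
        strength=s,
        clustering=cw,
        degree_ccdf=ccdf([k[n_] for n_ in active]) if active else [],
        strength_ccdf=ccdf([s[n_] for n_ in active]) if active else [],
        isolated=iso,
    )
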