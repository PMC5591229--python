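"""Two-layer plant–VOC graph and its one-mode projections.

The incidence matrix A (species × VOC) defines a bipartite graph: a plant
is linked to every VOC it emits above threshold.  The plants projection
has weight w_ij = number of VOCs shared by species i and j (the
off-diagonal of A·Aᵀ); the VOC projection weights by the number of plants
emitting both compounds (Aᵀ·A).  Plants sharing nothing stay in the graph
as isolated nodes — their emergence is informative, not an artifact.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .preprocessing import IncidenceMatrix

__all__ = [
    "build_bipartite",
    "project_plants",
    "project_vocs",
    "rescale_weights",
    "filter_edges",
]

PLANT_LAYER = "plant"
VOC_LAYER = "voc"


def build_bipartite(inc: IncidenceMatrix) -> nx.Graph:
    """Bipartite graph with one edge per 1-bit; degree-0 nodes retained."""
    g = nx.Graph(kind="bipartite")
    g.add_nodes_from(inc.species_ids, layer=PLANT_LAYER, bipartite=0)
    g.add_nodes_from(inc.voc_ids, layer=VOC_LAYER, bipartite=1)
    rows, cols = np.nonzero(inc.bits)
    g.add_edges_from(
        (inc.species_ids[i], inc.voc_ids[j]) for i, j in zip(rows.tolist(), cols.tolist())
    )
    g.graph["scheme"] = dict(inc.scheme)
    return g


def _biadjacency(bg: nx.Graph) -> tuple[list[str], list[str], np.ndarray]:
    plants = [n for n, d in bg.nodes(data=True) if d.get("layer") == PLANT_LAYER]
    vocs = [n for n, d in bg.nodes(data=True) if d.get("layer") == VOC_LAYER]
    a = np.zeros((len(plants), len(vocs)), dtype=np.int64)
    vidx = {v: j for j, v in enumerate(vocs)}
    pidx = {p: i for i, p in enumerate(plants)}
    for u, v in bg.edges():
        if u in pidx:
            a[pidx[u], vidx[v]] = 1
        else:
            a[pidx[v], vidx[u]] = 1
    return plants, vocs, a


def _project(labels: list[str], a: np.ndarray) -> nx.Graph:
    w = a @ a.T
    np.fill_diagonal(w, 0)
    g = nx.Graph()
    g.add_nodes_from(labels)
    ii, jj = np.nonzero(np.triu(w, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(labels[i], labels[j], weight=int(w[i, j]))
    return g


def project_plants(bg: nx.Graph) -> nx.Graph:
    """One-mode plants graph: w_ij = |shared VOCs| (off-diagonal of A·Aᵀ)."""
    plants, _, a = _biadjacency(bg)
    g = _project(plants, a)
    g.graph["layer"] = PLANT_LAYER
    return g


def project_vocs(bg: nx.Graph) -> nx.Graph:
    """One-mode VOC graph: w_fg = |plants emitting both| (off-diagonal of Aᵀ·A)."""
    _, vocs, a = _biadjacency(bg)
    g = _project(vocs, a.T)
    g.graph["layer"] = VOC_LAYER
    return g


def rescale_weights(g: nx.Graph) -> nx.Graph:
    """Min–max rescale edge weights to [0, 1] over the existing edges.

    w' = (w − w_min) / (w_max − w_min); when all weights coincide every
    edge gets weight 1 (the degenerate range collapses upward so that
    filtering at any threshold ≤ 1 keeps the graph intact).
    """
    if g.number_of_edges() == 0:
        raise ValueError("cannot rescale an edgeless graph")
    weights = np.array([w for _, _, w in g.edges(data="weight", default=1)], dtype=float)
    w_min, w_max = weights.min(), weights.max()
    out = g.copy()
    for u, v, w in g.edges(data="weight", default=1):
        if w_max == w_min:
            out[u][v]["weight"] = 1.0
        else:
            out[u][v]["weight"] = (w - w_min) / (w_max - w_min)
    out.graph["rescaled"] = True
    return out


def filter_edges(g: nx.Graph, min_w: float) -> nx.Graph:
    """Keep edges with rescaled weight ≥ min_w; nodes are never dropped.

    The closed inequality means min_w = 1 retains the maximum-weight edges.
    The result records its surviving edge count and whether the subgraph on
    non-isolated nodes is connected.
    """
    if not (0 <= min_w <= 1):
        raise ValueError("min_w must lie in [0, 1]")
    out = nx.Graph(**g.graph)
    out.add_nodes_from(g.nodes(data=True))
    for u, v, w in g.edges(data="weight", default=1):
        if w >= min_w:
            out.add_edge(u, v, weight=w)
    active = [n for n in out if out.degree(n) > 0]
    out.graph["min_w"] = float(min_w)
    out.graph["n_edges"] = out.number_of_edges()
    out.graph["is_connected"] = (
        nx.is_connected(out.subgraph(active)) if active else False
    )
    return out
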