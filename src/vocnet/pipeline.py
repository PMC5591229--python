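"""End-to-end convenience: emission matrix → communities.

The canonical chain is: binarize (third-quartile rule), build the
bipartite plant–VOC graph, project onto plants, and detect communities.
Stochastic algorithms are run over several seeds and the maximum-
modularity run is kept.
"""

from __future__ import annotations

import networkx as nx

from .bipartite import build_bipartite, project_plants
from .community import Partition, detect, louvain
from .io import EmissionMatrix
from .preprocessing import binarize_fixed, binarize_third_quartile

__all__ = ["plants_graph", "best_of_seeds", "cluster_plants"]


def plants_graph(matrix: EmissionMatrix, scheme: str = "q3",
                 threshold: float = 1.0) -> nx.Graph:
    """Plants projection under the chosen binarization scheme."""
    if scheme == "q3":
        inc = binarize_third_quartile(matrix)
    elif scheme == "fixed":
        inc = binarize_fixed(matrix, threshold)
    else:
        raise ValueError(f"unknown binarization scheme {scheme!r}")
    return project_plants(build_bipartite(inc))


def best_of_seeds(g: nx.Graph, algorithm: str = "louvain", n_seeds: int = 10,
                  base_seed: int = 0) -> Partition:
    """Run a seeded algorithm ``n_seeds`` times and keep the max-Q partition."""
    best = None
    for s in range(n_seeds):
        p = detect(g, algorithm, seed=base_seed + s)
        if best is None or (p.quality or 0) > (best.quality or 0):
            best = p
    return best


def cluster_plants(matrix: EmissionMatrix, scheme: str = "q3",
                   threshold: float = 1.0, algorithm: str = "louvain",
                   n_seeds: int = 10, base_seed: int = 0) -> tuple[nx.Graph, Partition]:
    """Full pipeline: binarize, project, detect (best of ``n_seeds`` runs)."""
    g = plants_graph(matrix, scheme=scheme, threshold=threshold)
    if g.number_of_edges() == 0:
        # nothing above threshold: every species is its own (isolated) community
        return g, Partition({n: i for i, n in enumerate(g)}, algorithm=algorithm)
    return g, best_of_seeds(g, algorithm=algorithm, n_seeds=n_seeds,
                            base_seed=base_seed)
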