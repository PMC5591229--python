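"""Weighted modularity and multi-algorithm community detection.

Modularity of a partition on a weighted graph,

    Q = (1/2m) Σ_vw [A_vw − k_v k_w / (2m)] δ(c_v, c_w) = Σ_i (e_ii − a_i²),

is evaluated on the weighted adjacency (A_vw = w_vw, k_v = strength,
m = total edge weight).  Four detection algorithms are provided — Louvain
multilevel optimisation (BL), Clauset–Newman–Moore fast greedy
agglomeration (FG), the Pons–Latapy random-walk method (WT), and
asynchronous label propagation (LP) — together with an exhaustive-search
oracle for tiny graphs, the edge-weight filtering sweep, and a
cross-algorithm consensus report.  Agreement across independent heuristics
is what makes a clustering trustworthy on noisy emission data: no single
run is taken at face value.

Isolated nodes are placed in singleton communities by every algorithm;
reporting later merges them into one "isolated" pseudo-cluster.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .bipartite import filter_edges

__all__ = [
    "Partition",
    "modularity",
    "modularity_double_sum",
    "louvain",
    "fast_greedy",
    "walktrap",
    "label_propagation",
    "brute_force_best_partition",
    "filter_sweep",
    "SweepRow",
    "consensus",
    "ConsensusReport",
]


@dataclass
class Partition:
    """Node → community assignment with provenance.

    Community ids are dense integers 0..n−1; ``quality`` is the weighted
    modularity of this partition on the graph it was computed from.
    """

    membership: dict
    algorithm: str = "unknown"
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    quality: float | None = None

    def __post_init__(self) -> None:
        self.membership = _dense_relabel(self.membership)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return [out[c] for c in sorted(out)]

    def labels(self, nodes) -> list[int]:
        return [self.membership[n] for n in nodes]


def _dense_relabel(membership: dict) -> dict:
    remap: dict = {}
    out = {}
    for n in membership:
        c = membership[n]
        if c not in remap:
            remap[c] = len(remap)
        out[n] = remap[c]
    return out


# -- modularity -------------------------------------------------------------

def _weights(g: nx.Graph, weighted: bool = True):
    if weighted:
        return {(u, v): float(w) for u, v, w in g.edges(data="weight", default=1)}
    return {(u, v): 1.0 for u, v in g.edges()}


def modularity(g: nx.Graph, p: Partition | dict, weighted: bool = True) -> float:
    """Weighted modularity via the community-sum form Σ_i (e_ii − a_i²)."""
    membership = p.membership if isinstance(p, Partition) else p
    missing = [n for n in g if n not in membership]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    w = _weights(g, weighted)
    m = sum(w.values())
    if m <= 0:
        raise ValueError("modularity of an edgeless graph is undefined")
    e_in: dict = {}
    a: dict = {}
    for (u, v), wuv in w.items():
        cu, cv = membership[u], membership[v]
        if cu == cv:
            e_in[cu] = e_in.get(cu, 0.0) + wuv
        a[cu] = a.get(cu, 0.0) + wuv
        a[cv] = a.get(cv, 0.0) + wuv
    q = 0.0
    for c in set(membership.values()):
        q += e_in.get(c, 0.0) / m - (a.get(c, 0.0) / (2.0 * m)) ** 2
    return q


def modularity_double_sum(g: nx.Graph, p: Partition | dict, weighted: bool = True) -> float:
    """Modularity via the explicit double sum over node pairs (O(N²) check)."""
    membership = p.membership if isinstance(p, Partition) else p
    nodes = list(g)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    aij = np.zeros((n, n))
    for (u, v), wuv in _weights(g, weighted).items():
        aij[idx[u], idx[v]] = wuv
        aij[idx[v], idx[u]] = wuv
    k = aij.sum(axis=1)
    m2 = aij.sum()  # 2m
    if m2 <= 0:
        raise ValueError("modularity of an edgeless graph is undefined")
    labels = np.array([membership[n_] for n_ in nodes])
    delta = labels[:, None] == labels[None, :]
    return float(((aij - np.outer(k, k) / m2) * delta).sum() / m2)


# -- Louvain ----------------------------------------------------------------

def louvain(g: nx.Graph, seed: int = 0, weighted: bool = True) -> Partition:
    """Louvain multilevel modularity optimisation (deterministic per seed).

    Phase one moves each node to the neighboring community with the
    largest modularity gain until no move helps; phase two collapses
    communities into super-nodes and repeats.  Node visiting order is
    shuffled from the seed, which is the only source of run-to-run
    variability.
    """
    rng = random.Random(seed)
    nodes = list(g)
    # adjacency with self-loop weights for aggregated levels
    adj: dict = {n: {} for n in nodes}
    for u, v, w in g.edges(data="weight", default=1):
        w = float(w) if weighted else 1.0
        adj[u][v] = adj[u].get(v, 0.0) + w
        adj[v][u] = adj[v].get(u, 0.0) + w
    membership = {n: n for n in nodes}  # original node -> current super-node
    while True:
        part, improved = _louvain_one_level(adj, rng)
        membership = {n: part[membership[n]] for n in membership}
        if not improved:
            break
        adj = _aggregate(adj, part)
    p = Partition(membership, algorithm="louvain", seed=seed,
                  parameters={"weighted": weighted})
    p.quality = modularity(g, p, weighted=weighted) if g.number_of_edges() else None
    return p


def _louvain_one_level(adj: dict, rng: random.Random) -> tuple[dict, bool]:
    nodes = list(adj)
    comm = {n: i for i, n in enumerate(nodes)}
    self_w = {n: adj[n].get(n, 0.0) for n in nodes}
    k = {n: sum(w for v, w in adj[n].items() if v != n) + 2 * self_w[n] for n in nodes}
    m2 = sum(k.values())  # 2m
    if m2 <= 0:
        return comm, False
    sigma_tot = {comm[n]: k[n] for n in nodes}
    improved = False
    moved = True
    while moved:
        moved = False
        order = nodes[:]
        rng.shuffle(order)
        for n in order:
            cn = comm[n]
            # weight from n to each neighboring community (self-loops excluded)
            links: dict = {}
            for v, w in adj[n].items():
                if v == n:
                    continue
                links[comm[v]] = links.get(comm[v], 0.0) + w
            sigma_tot[cn] -= k[n]
            best_c, best_gain = cn, links.get(cn, 0.0) - sigma_tot[cn] * k[n] / m2
            for c, w_in in links.items():
                if c == cn:
                    continue
                gain = w_in - sigma_tot[c] * k[n] / m2
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + k[n]
            if best_c != cn:
                comm[n] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(adj: dict, part: dict) -> dict:
    agg: dict = {}
    for u in adj:
        cu = part[u]
        agg.setdefault(cu, {})
        for v, w in adj[u].items():
            cv = part[v]
            if u == v:
                agg[cu][cu] = agg[cu].get(cu, 0.0) + w
            elif cu == cv:
                # internal edge appears twice in adj; halve into one self-loop
                agg[cu][cu] = agg[cu].get(cu, 0.0) + w / 2.0
            else:
                # symmetric entries are visited once from each endpoint
                agg[cu][cv] = agg[cu].get(cv, 0.0) + w
    return agg


# -- fast greedy (CNM) ------------------------------------------------------

def fast_greedy(g: nx.Graph, weighted: bool = True) -> Partition:
    """Clauset–Newman–Moore greedy agglomeration with a merge dendrogram.

    Starts from singletons and repeatedly merges the edge-connected
    community pair with the largest modularity change ΔQ = 2(e_ij − a_i a_j)
    until no connected pair remains (N − 1 merges on a connected graph);
    the returned partition cuts the dendrogram at the maximum-Q step.  The
    merge list is stored in ``parameters["dendrogram"]``.
    """
    nodes = list(g)
    if g.number_of_edges() == 0:
        raise ValueError("fast greedy needs at least one edge")
    w = _weights(g, weighted)
    m = sum(w.values())
    comm_of = {n: i for i, n in enumerate(nodes)}
    members: dict = {i: {n} for i, n in enumerate(nodes)}
    e: dict = {i: {} for i in members}  # e[i][j] = fraction of weight between i,j
    a = {i: 0.0 for i in members}
    for (u, v), wuv in w.items():
        cu, cv = comm_of[u], comm_of[v]
        frac = wuv / m
        if cu == cv:
            e[cu][cu] = e[cu].get(cu, 0.0) + frac
        else:
            e[cu][cv] = e[cu].get(cv, 0.0) + frac
            e[cv][cu] = e[cv].get(cu, 0.0) + frac
        a[cu] += frac / 2.0 + (frac / 2.0 if cu == cv else 0.0)
        if cu != cv:
            a[cv] += frac / 2.0
    q = sum(e[i].get(i, 0.0) for i in members) - sum(ai * ai for ai in a.values())
    best_q, best_snapshot = q, dict(comm_of)
    dendrogram: list[tuple] = []
    while True:
        best = None
        for i in members:
            for j, eij in e[i].items():
                if j <= i:
                    continue
                # eij stores the full between-fraction f_ij, so the CNM
                # gain 2(e_ij − a_i a_j) with halved e_ij reads f_ij − 2 a_i a_j
                dq = eij - 2.0 * a[i] * a[j]
                if best is None or dq > best[0] + 1e-15:
                    best = (dq, i, j)
        if best is None:
            break
        dq, i, j = best
        dendrogram.append((sorted(members[i])[0], sorted(members[j])[0], dq))
        # merge j into i
        q += dq
        e[i][i] = e[i].get(i, 0.0) + e[j].get(j, 0.0) + e[i].get(j, 0.0)
        for h, ejh in e[j].items():
            if h in (i, j):
                continue
            e[i][h] = e[i].get(h, 0.0) + ejh
            e[h][i] = e[h].get(i, 0.0) + ejh
            del e[h][j]
        e[i].pop(j, None)
        e.pop(j)
        for h in e:
            e[h].pop(j, None)
        a[i] += a[j]
        del a[j]
        members[i] |= members.pop(j)
        for n in members[i]:
            comm_of[n] = i
        if q > best_q + 1e-12:
            best_q, best_snapshot = q, dict(comm_of)
    p = Partition(best_snapshot, algorithm="fastgreedy",
                  parameters={"weighted": weighted, "dendrogram": dendrogram})
    p.quality = modularity(g, p, weighted=weighted)
    return p


# -- walktrap ---------------------------------------------------------------

def walktrap(g: nx.Graph, t: int = 4, weighted: bool = True) -> Partition:
    """Pons–Latapy random-walk agglomeration, cut at maximum modularity.

    Short walks (t steps, default 4) tend to stay inside a community, so
    the Euclidean distance between degree-normalized t-step transition
    profiles separates communities.  Ward-style agglomeration merges the
    adjacent community pair with the smallest within-variance increase;
    the dendrogram is cut at the partition of maximal weighted modularity.
    Degree-0 nodes are excluded from the walk and kept as singletons.
    """
    if g.number_of_edges() == 0:
        raise ValueError("walktrap needs at least one edge")
    active = [n for n in g if g.degree(n) > 0]
    idx = {n: i for i, n in enumerate(active)}
    n = len(active)
    adj = np.zeros((n, n))
    for u, v, w in g.edges(data="weight", default=1):
        w = float(w) if weighted else 1.0
        adj[idx[u], idx[v]] = w
        adj[idx[v], idx[u]] = w
    deg = adj.sum(axis=1)
    pt = np.linalg.matrix_power(adj / deg[:, None], t)
    inv_sqrt_d = 1.0 / np.sqrt(deg)

    comm_of = {i: i for i in range(n)}
    members: dict = {i: [i] for i in range(n)}
    prof = {i: pt[i] * inv_sqrt_d for i in range(n)}  # D^{-1/2} P^t_i.
    neighbors: dict = {i: set() for i in range(n)}
    for u, v in g.edges():
        if g.degree(u) and g.degree(v) and u != v:
            i, j = idx[u], idx[v]
            if i != j:
                neighbors[i].add(j)
                neighbors[j].add(i)

    snapshots = [dict(comm_of)]
    while True:
        best = None
        for i in members:
            for j in neighbors[i]:
                if j <= i:
                    continue
                ni, nj = len(members[i]), len(members[j])
                d2 = float(((prof[i] - prof[j]) ** 2).sum())
                ds = (ni * nj) / (ni + nj) / n * d2
                if best is None or ds < best[0] - 1e-15:
                    best = (ds, i, j)
        if best is None:
            break
        _, i, j = best
        ni, nj = len(members[i]), len(members[j])
        prof[i] = (ni * prof[i] + nj * prof[j]) / (ni + nj)
        members[i].extend(members.pop(j))
        del prof[j]
        neighbors[i] |= neighbors.pop(j)
        neighbors[i].discard(i)
        neighbors[i].discard(j)
        for h in neighbors:
            if j in neighbors[h]:
                neighbors[h].discard(j)
                if h != i:
                    neighbors[h].add(i)
        for v_ in members[i]:
            comm_of[v_] = i
        snapshots.append(dict(comm_of))

    best_q, best_snap = -np.inf, snapshots[0]
    for snap in snapshots:
        membership = {active[i]: snap[i] for i in range(n)}
        for extra, node in enumerate(set(g) - set(active)):
            membership[node] = n + extra
        q = modularity(g, membership, weighted=weighted)
        if q > best_q + 1e-12:
            best_q, best_snap = q, snap
    membership = {active[i]: best_snap[i] for i in range(n)}
    for extra, node in enumerate(sorted(set(g) - set(active), key=str)):
        membership[node] = n + extra
    p = Partition(membership, algorithm="walktrap",
                  parameters={"t": t, "weighted": weighted})
    p.quality = best_q
    return p


# -- label propagation ------------------------------------------------------

def label_propagation(g: nx.Graph, seed: int = 0, weighted: bool = True,
                      max_sweeps: int = 1000) -> Partition:
    """Asynchronous weighted label propagation (deterministic per seed).

    Every node starts with a unique label; in seed-shuffled order each
    node adopts the label with the largest edge-weight-weighted vote among
    its neighbors, ties broken uniformly at random from the seed.  Stops
    when every node's label is already among its neighborhood's maximal
    labels (with a hard sweep cap to guarantee halting).
    """
    rng = random.Random(seed)
    labels = {n: i for i, n in enumerate(g)}
    nodes = list(g)
    for _ in range(max_sweeps):
        order = nodes[:]
        rng.shuffle(order)
        changed = False
        for n in order:
            if g.degree(n) == 0:
                continue
            votes: dict = {}
            for v in g[n]:
                w = float(g[n][v].get("weight", 1)) if weighted else 1.0
                votes[labels[v]] = votes.get(labels[v], 0.0) + w
            top = max(votes.values())
            winners = sorted(lab for lab, w in votes.items() if w >= top - 1e-12)
            if labels[n] not in winners:
                labels[n] = rng.choice(winners)
                changed = True
        if not changed:
            break
    p = Partition(labels, algorithm="labelprop", seed=seed,
                  parameters={"weighted": weighted})
    p.quality = modularity(g, p, weighted=weighted) if g.number_of_edges() else None
    return p


# -- exhaustive oracle ------------------------------------------------------

def _set_partitions(items: list):
    """All set partitions via restricted-growth strings."""
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n
    maxes = [0] * n
    while True:
        groups: dict = {}
        for item, c in zip(items, rgs):
            groups.setdefault(c, []).append(item)
        yield list(groups.values())
        i = n - 1
        while i > 0 and rgs[i] == maxes[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        rgs[i] += 1
        maxes[i] = max(maxes[i - 1], rgs[i])
        for j in range(i + 1, n):
            rgs[j] = 0
            maxes[j] = maxes[j - 1]


def brute_force_best_partition(g: nx.Graph, weighted: bool = True) -> Partition:
    """Exhaustive maximum-modularity partition (test oracle, N ≤ 10)."""
    nodes = list(g)
    if len(nodes) > 10:
        raise ValueError("exhaustive search is limited to graphs with <= 10 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("modularity of an edgeless graph is undefined")
    w = _weights(g, weighted)
    m = sum(w.values())
    strength: dict = {n: 0.0 for n in nodes}
    for (u, v), wuv in w.items():
        strength[u] += wuv
        strength[v] += wuv
    edges = [(u, v, wuv) for (u, v), wuv in w.items()]
    best_q, best_m = -np.inf, None
    for blocks in _set_partitions(nodes):
        membership = {}
        for c, block in enumerate(blocks):
            for n in block:
                membership[n] = c
        e_in = 0.0
        a2 = 0.0
        for block in blocks:
            a2 += (sum(strength[n] for n in block) / (2.0 * m)) ** 2
        for u, v, wuv in edges:
            if membership[u] == membership[v]:
                e_in += wuv
        q = e_in / m - a2
        if q > best_q:
            best_q, best_m = q, membership
    p = Partition(best_m, algorithm="brute_force")
    p.quality = best_q
    return p


# -- sweep & consensus ------------------------------------------------------

ALGORITHMS = ("fastgreedy", "walktrap", "louvain", "labelprop")


def detect(g: nx.Graph, algorithm: str, seed: int = 0, t: int = 4,
           weighted: bool = True) -> Partition:
    """Dispatch one of the four detection algorithms by name."""
    if algorithm in ("louvain", "blondel", "bl"):
        return louvain(g, seed=seed, weighted=weighted)
    if algorithm in ("fastgreedy", "fg"):
        return fast_greedy(g, weighted=weighted)
    if algorithm in ("walktrap", "wt"):
        return walktrap(g, t=t, weighted=weighted)
    if algorithm in ("labelprop", "lp"):
        return label_propagation(g, seed=seed, weighted=weighted)
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class SweepRow:
    """One row of the edge-weight filtering sweep.

    ``n_communities`` counts non-singleton community structure as the raw
    number of communities each algorithm reports (isolated nodes counted
    as singletons).
    """

    min_w: float
    n_edges: int
    n_active: int
    is_connected: bool
    n_communities: dict


def filter_sweep(g: nx.Graph, thresholds, seed: int = 0, t: int = 4) -> list[SweepRow]:
    """Run all four algorithms on each weight-filtered version of ``g``.

    ``g`` must carry rescaled weights in [0, 1].  For each threshold the
    row records surviving edges, non-isolated node count, connectivity of
    the active subgraph, and the community count per algorithm.
    """
    rows = []
    for min_w in thresholds:
        sub = filter_edges(g, min_w)
        counts = {}
        for alg in ALGORITHMS:
            if sub.number_of_edges() == 0:
                counts[alg] = sub.number_of_nodes()
            else:
                counts[alg] = detect(sub, alg, seed=seed, t=t).n_communities
        active = sum(1 for n in sub if sub.degree(n) > 0)
        rows.append(SweepRow(
            min_w=float(min_w),
            n_edges=sub.number_of_edges(),
            n_active=active,
            is_connected=bool(sub.graph["is_connected"]),
            n_communities=counts,
        ))
    return rows


def sweep_table(rows: list[SweepRow]):
    """Sweep rows as a DataFrame shaped like the published filtering table."""
    import pandas as pd

    return pd.DataFrame([
        {
            "FG": r.n_communities.get("fastgreedy"),
            "WT": r.n_communities.get("walktrap"),
            "BL": r.n_communities.get("louvain"),
            "LP": r.n_communities.get("labelprop"),
            "w_resc": r.min_w,
            "E": r.n_edges,
            "N": r.n_active,
            "is.connected": r.is_connected,
        }
        for r in rows
    ])


@dataclass
class ConsensusReport:
    algorithms: list
    ari: np.ndarray
    nmi: np.ndarray
    stable_pairs: set
    retained: Partition
    robust: bool
    min_ari: float


def consensus(partitions: list[Partition], g: nx.Graph | None = None,
              ari_threshold: float = 0.7) -> ConsensusReport:
    """Cross-algorithm agreement and the retained partition.

    Pairwise ARI/NMI matrices over all input partitions; co-membership
    pairs on which every algorithm agrees; the retained partition is the
    maximum-modularity input, flagged robust iff the minimum pairwise ARI
    reaches ``ari_threshold``.
    """
    if len(partitions) < 2:
        raise ValueError("consensus needs at least 2 partitions")
    node_sets = [frozenset(p.membership) for p in partitions]
    if len(set(node_sets)) != 1:
        raise ValueError("partitions cover different node sets")
    nodes = sorted(node_sets[0], key=str)
    labelings = [p.labels(nodes) for p in partitions]
    k = len(partitions)
    ari = np.eye(k)
    nmi = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        ari[i, j] = ari[j, i] = adjusted_rand_score(labelings[i], labelings[j])
        nmi[i, j] = nmi[j, i] = normalized_mutual_info_score(labelings[i], labelings[j])
    stable = set()
    for a, b in itertools.combinations(range(len(nodes)), 2):
        if all(lab[a] == lab[b] for lab in labelings):
            stable.add((nodes[a], nodes[b]))
    qualities = []
    for p in partitions:
        if p.quality is not None:
            qualities.append(p.quality)
        elif g is not None:
            qualities.append(modularity(g, p))
        else:
            qualities.append(-np.inf)
    retained = partitions[int(np.argmax(qualities))]
    off_diag = ari[~np.eye(k, dtype=bool)]
    min_ari = float(off_diag.min())
    return ConsensusReport(
        algorithms=[p.algorithm for p in partitions],
        ari=ari, nmi=nmi, stable_pairs=stable, retained=retained,
        robust=min_ari >= ari_threshold, min_ari=min_ari,
    )
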