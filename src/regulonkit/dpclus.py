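"""Overlapping, density-constrained graph clustering.

A from-scratch greedy clustering in the density/periphery style introduced
for protein interaction networks (DPClus): clusters are grown from
high-degree seeds, one node at a time, under two constraints —

* cluster density d = 2|E|/(k(k-1)) must stay at or above ``d_min``;
* every node's cluster property cp = |E(v, C)| / (d(C) * |C \\ {v}|), its
  in-cluster connectivity normalized by cluster density and size, must stay
  at or above ``cp_min`` (this ejects sparsely connected periphery nodes
  even when the average density passes).

The procedure is fully deterministic: seed choice is by highest degree then
lexicographic node id; growth candidates are prioritized by edges into the
cluster, then total degree, then id; periphery ejection removes the
lowest-cp member first.  In overlapping mode emitted members are retired as
future seeds but remain available as growth candidates for later clusters;
in non-overlapping mode they are removed from the working graph outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ClusterParams:
    d_min: float = 0.75
    cp_min: float = 0.75
    min_size: int = 3
    overlapping: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.d_min <= 1.0:
            raise ValueError("d_min must be in (0, 1]")
        if not 0.0 < self.cp_min <= 1.0:
            raise ValueError("cp_min must be in (0, 1]")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")


@dataclass
class Cluster:
    cluster_id: int
    members: frozenset
    density: float
    cp: dict = field(default_factory=dict)
    seed: str = ""

    def __len__(self) -> int:
        return len(self.members)


def _adjacency(graph) -> dict:
    """Accept a CoexpressionNetwork, a networkx Graph, or a dict-of-sets."""
    if hasattr(graph, "adjacency") and not isinstance(graph, dict):
        try:
            return {n: set(v) for n, v in graph.adjacency().items()}
        except TypeError:
            # networkx adjacency() yields (node, neighbor-dict) pairs
            return {n: set(nbrs) for n, nbrs in graph.adjacency()}
    if isinstance(graph, dict):
        return {n: set(v) for n, v in graph.items()}
    raise TypeError(f"unsupported graph type {type(graph)!r}")


def _edge_count(members: set, adj: dict) -> int:
    return sum(len(adj[v] & members) for v in members) // 2


def density(members, graph) -> float:
    """Induced-subgraph density 2|E|/(k(k-1)); error for singletons."""
    members = set(members)
    k = len(members)
    if k < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    adj = _adjacency(graph)
    return 2.0 * _edge_count(members, adj) / (k * (k - 1))


def cluster_property(v, members, graph) -> float:
    """cp of node v with respect to a member set.

    cp = |E(v, members \\ {v})| / (density(members) * |members \\ {v}|).
    The normalization set excludes v when v is itself a member.  Defined as
    0 when the cluster density is 0.
    """
    members = set(members)
    adj = _adjacency(graph)
    return _cp(v, members, adj, _density_of(members, adj))


def _density_of(members: set, adj: dict) -> float:
    k = len(members)
    if k < 2:
        return 1.0  # singleton: treated as fully dense for candidate checks
    return 2.0 * _edge_count(members, adj) / (k * (k - 1))


def _cp(v, members: set, adj: dict, dens: float) -> float:
    others = members - {v}
    if not others:
        return 0.0
    if dens == 0.0:
        return 0.0
    return len(adj[v] & others) / (dens * len(others))


def cluster_graph(graph, params: ClusterParams | None = None) -> list[Cluster]:
    """Run the greedy density clustering over the whole graph.

    Returns clusters sorted by size descending then seed id, with 1-based
    ids, recomputed density and per-member cp.  An edgeless graph yields an
    empty list.  The procedure is deterministic.
    """
    params = params or ClusterParams()
    full_adj = _adjacency(graph)
    adj = {n: set(v) for n, v in full_adj.items()}  # working copy
    finished: set = set()
    raw: list[tuple[set, str]] = []

    while True:
        unfinished = [n for n in adj if n not in finished]
        if not unfinished:
            break
        seed = min(unfinished, key=lambda n: (-len(adj[n]), n))
        if not adj[seed]:
            finished.add(seed)
            continue

        members = {seed}
        n_edges = 0
        # --- growth ---
        while True:
            candidates = set().union(*(adj[m] for m in members)) - members
            if not candidates:
                break
            dens = _density_of(members, adj)
            k = len(members)
            added = False
            for cand in sorted(
                candidates,
                key=lambda c: (-len(adj[c] & members), -len(adj[c]), c),
            ):
                e_in = len(adj[cand] & members)
                new_density = 2.0 * (n_edges + e_in) / ((k + 1) * k)
                if new_density < params.d_min:
                    continue
                if _cp(cand, members, adj, dens) < params.cp_min:
                    continue
                members.add(cand)
                n_edges += e_in
                added = True
                break
            if not added:
                break

        # --- periphery ejection (after growth stalls) ---
        while len(members) >= 2:
            dens = 2.0 * n_edges / (len(members) * (len(members) - 1))
            cps = {v: _cp(v, members, adj, dens) for v in members}
            worst = min(members, key=lambda v: (cps[v], v))
            if cps[worst] >= params.cp_min and dens >= params.d_min:
                break
            n_edges -= len(adj[worst] & members)
            members.discard(worst)

        emitted = len(members) >= params.min_size
        finished.add(seed)  # the seed never re-seeds, even if it was ejected
        if emitted:
            raw.append((set(members), seed))
            if params.overlapping:
                finished |= members
            else:
                finished |= members
                for v in members:
                    for nb in adj[v]:
                        adj[nb].discard(v)
                for v in members:
                    del adj[v]
        else:
            finished.add(seed)

    raw.sort(key=lambda ms: (-len(ms[0]), ms[1]))
    clusters = []
    for i, (members, seed) in enumerate(raw, start=1):
        k = len(members)
        dens = 2.0 * _edge_count(members, full_adj) / (k * (k - 1))
        cps = {v: _cp(v, members, full_adj, dens) for v in members}
        clusters.append(
            Cluster(
                cluster_id=i,
                members=frozenset(members),
                density=dens,
                cp=cps,
                seed=seed,
            )
        )
    return clusters
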