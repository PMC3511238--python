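"""Seed-set expansion into a co-expression network, with threshold diagnostics.

Starting from a seed list of probesets (genes known to respond to the
regulators of interest), the merged compendium is scanned for probesets whose
Spearman correlation with any seed reaches a cutoff; the expanded member set
is then wired into a network with an edge wherever a pair correlates at or
above the cutoff.  Only positive correlations create edges — the clusters
sought downstream are positively co-expressed regulons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import DataError, PromoterSet, ProbesetGeneMap, SeedSet, map_cluster_to_genes
from .normalize import MergedMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Probeset nodes with rho-weighted edges at or above a threshold.

    Edges are stored once per unordered pair, keyed (a, b) with a < b;
    self-edges are never present.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]
    threshold: float
    seed_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if a > b:
                raise ValueError(f"edge key ({a}, {b}) not in sorted order")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
            if w < self.threshold:
                raise ValueError(f"edge ({a}, {b}) weight {w} below threshold")

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class ThresholdRow:
    cutoff: float
    n_probesets: int
    n_genes: int
    n_with_promoter: int
    mean_motifs_per_gene: float
    more_than: dict[int, int]  # k -> number of genes with > k motifs


@dataclass
class ThresholdReport:
    motif_name: str
    rows: list[ThresholdRow]

    def to_frame(self):
        import pandas as pd

        recs = []
        for r in self.rows:
            rec = {
                "cutoff": r.cutoff,
                "n_probesets": r.n_probesets,
                "n_genes": r.n_genes,
                "n_with_promoter": r.n_with_promoter,
                "mean_motifs_per_gene": r.mean_motifs_per_gene,
            }
            for k, v in r.more_than.items():
                rec[f"genes_gt{k}_motifs"] = v
            recs.append(rec)
        return pd.DataFrame(recs)


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered rank rows and their norms (0 for constant rows)."""
    ranks = stats.rankdata(values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    return centered, norms


def expand_seeds(merged: MergedMatrix, seeds: SeedSet, cutoff: float) -> list[str]:
    """Seeds plus every probeset whose max-over-seeds Spearman rho reaches
    the cutoff ("any seed" aggregation; a mean-over-seeds alternative is
    provided via ``aggregate``).

    Order is deterministic: seeds first (input order), then additional
    members sorted by probeset id.  Missing seeds are logged; an entirely
    absent seed set is an error.
    """
    return _expand(merged, seeds, cutoff, aggregate="max")


def _expand(merged: MergedMatrix, seeds: SeedSet, cutoff: float, aggregate: str = "max") -> list[str]:
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    present = [s for s in seeds if s in set(merged.probeset_ids)]
    missing = [s for s in seeds if s not in set(merged.probeset_ids)]
    if missing:
        logger.info("expand_seeds: %d seed(s) missing from merged matrix", len(missing))
    if not present:
        raise DataError("no seed probeset present in the merged matrix")
    centered, norms = _rank_rows(merged.values)
    idx = {p: i for i, p in enumerate(merged.probeset_ids)}
    seed_rows = np.array([idx[s] for s in present])
    with np.errstate(invalid="ignore", divide="ignore"):
        # rho matrix: seeds x all probesets, via normalized rank rows
        denom = np.outer(norms[seed_rows], norms)
        rho = (centered[seed_rows] @ centered.T) / denom
    rho[~np.isfinite(rho)] = -np.inf
    agg = rho.max(axis=0) if aggregate == "max" else rho.mean(axis=0)
    members = list(present)
    seed_set = set(present)
    extra = [
        p
        for p in merged.probeset_ids
        if p not in seed_set and agg[idx[p]] >= cutoff - 1e-12
    ]
    members.extend(sorted(extra))
    return members


def build_network(merged: MergedMatrix, members: list[str], cutoff: float, seed_flags: dict[str, bool] | None = None) -> CoexpressionNetwork:
    """All-pairs Spearman among the members; an edge wherever signed rho is
    at or above the cutoff.  Nodes without edges are kept as isolates."""
    if len(members) < 2:
        raise ValueError("need at least 2 members to build a network")
    idx = {p: i for i, p in enumerate(merged.probeset_ids)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise DataError(f"members absent from merged matrix: {missing[:5]}")
    sub = merged.values[[idx[m] for m in members]]
    centered, norms = _rank_rows(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / np.outer(norms, norms)
    edges: dict[tuple[str, str], float] = {}
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            w = rho[i, j]
            if np.isfinite(w) and w >= cutoff - 1e-12:
                a, b = sorted((members[i], members[j]))
                edges[(a, b)] = float(w)
    return CoexpressionNetwork(
        nodes=list(members),
        edges=edges,
        threshold=cutoff,
        seed_flags=seed_flags or {},
    )


def threshold_report(
    merged: MergedMatrix,
    seeds: SeedSet,
    promoters: PromoterSet,
    probe_map: ProbesetGeneMap,
    motif,
    cutoffs: list[float],
    tail_ks: tuple[int, ...] = (3, 4, 5, 6, 7),
) -> ThresholdReport:
    """Per-cutoff network size and promoter motif abundance diagnostics.

    For each cutoff (descending): the expanded member count, the mean motif
    count per gene over genes with a promoter, and the number of genes with
    more than k motifs for k in ``tail_ks``.  Genes without a promoter are
    excluded from the motif columns and counted in the coverage column.
    """
    from .motifs import count_motif

    if list(cutoffs) != sorted(cutoffs, reverse=True):
        raise ValueError("cutoffs must be sorted descending")
    rows = []
    for cutoff in cutoffs:
        members = expand_seeds(merged, seeds, cutoff)
        genes, _ = map_cluster_to_genes(members, probe_map)
        counts = [
            count_motif(promoters[g], motif).count for g in genes if g in promoters
        ]
        n_cov = len(counts)
        mean = float(np.mean(counts)) if counts else 0.0
        rows.append(
            ThresholdRow(
                cutoff=cutoff,
                n_probesets=len(members),
                n_genes=len(genes),
                n_with_promoter=n_cov,
                mean_motifs_per_gene=mean,
                more_than={k: sum(1 for c in counts if c > k) for k in tail_ks},
            )
        )
    return ThresholdReport(motif_name=motif.name, rows=rows)


def pairwise_spearman(merged: MergedMatrix, members: list[str]) -> np.ndarray:
    """Symmetric Spearman rho matrix over the given members (NaN where a
    row is constant)."""
    idx = {p: i for i, p in enumerate(merged.probeset_ids)}
    sub = merged.values[[idx[m] for m in members]]
    centered, norms = _rank_rows(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / np.outer(norms, norms)
    return rho
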