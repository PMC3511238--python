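"""IUPAC motif counting, bootstrap pseudocluster enrichment, positional bias.

Motifs are fixed-length IUPAC strings; gapped dyads are written with runs of
N (e.g. ``CCTNNNNNNNTCC`` for CCT-n7-TCC).  Matches may overlap.  Enrichment
follows the pseudocluster bootstrap scheme used for promoter sets: B
same-size resamples (with replacement) are drawn from the cluster genes and
from a genomic background, the per-pseudocluster statistic is the mean motif
count per promoter, and a Welch two-sample t compares the two B-sized
collections of pseudocluster means.  These p-values are anti-conservative
(resampling inflates the effective sample size — a property of the
pseudocluster scheme itself); results carry B so users can judge.

Positional bias of a motif toward the transcription start site is tested by
a two-sided Fisher exact test on a proximal/distal occurrence table, with
the p-value computed by exact hypergeometric point-probability summation in
integer arithmetic.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

IUPAC_CLASSES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGTN",  # the only pattern letter that matches an N in sequence
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC pattern with a strand scanning mode.

    ``sense`` scans the promoter as written (the upstream strand); ``both``
    additionally scans the reverse complement, reporting those matches at
    forward coordinates with strand '-'.
    """

    name: str
    pattern: str
    strand_mode: str = "sense"

    def __post_init__(self) -> None:
        if len(self.pattern) < 3:
            raise ValueError("pattern must be at least 3 letters")
        bad = set(self.pattern.upper()) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)} in pattern")
        if self.strand_mode not in ("sense", "both"):
            raise ValueError("strand_mode must be 'sense' or 'both'")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def regex(self) -> re.Pattern:
        # lookahead so that overlapping matches are all reported
        body = "".join(f"[{IUPAC_CLASSES[c]}]" for c in self.pattern)
        return re.compile(f"(?=({body}))")


@dataclass
class MotifMatches:
    count: int
    positions: list[int]
    strands: list[str]


@dataclass
class MotifCountProfile:
    """Per-gene motif matches at 0-based positions from the promoter 5' end."""

    motif: MotifSpec
    per_gene: dict[str, MotifMatches] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {g: m.count for g, m in self.per_gene.items()}


@dataclass
class EnrichmentResult:
    motif_name: str
    cluster_id: int | str
    n: int
    B: int
    mean_cluster: float
    mean_background: float
    t_value: float
    p_two_sided: float
    seed: int
    degenerate: bool = False


@dataclass
class PositionalBiasResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # (cluster, background) x (proximal, distal)
    odds_ratio: float
    p: float
    degenerate: bool = False


def count_motif(seq: str, motif: MotifSpec) -> MotifMatches:
    """All (possibly overlapping) matches of the motif in a promoter.

    With ``strand_mode='both'`` the reverse complement is scanned too and
    its matches are mapped back to forward coordinates.  An N in the
    sequence matches only the pattern letter N.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters {sorted(bad)}")
    rx = motif.regex()
    hits = [(m.start(), "+") for m in rx.finditer(seq)]
    if motif.strand_mode == "both":
        m_len = len(motif.pattern)
        rc = reverse_complement(seq)
        for m in rx.finditer(rc):
            hits.append((len(seq) - m.start() - m_len, "-"))
        hits.sort()
    return MotifMatches(
        count=len(hits),
        positions=[p for p, _ in hits],
        strands=[s for _, s in hits],
    )


def profile_promoters(promoters, motif: MotifSpec, gene_ids=None) -> MotifCountProfile:
    """Count the motif over a promoter set (or a subset of gene ids)."""
    genes = gene_ids if gene_ids is not None else promoters.gene_ids
    return MotifCountProfile(
        motif=motif,
        per_gene={g: count_motif(promoters[g], motif) for g in genes if g in promoters},
    )


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    The p-value sums the hypergeometric point probabilities of every table
    with the same margins whose probability does not exceed the observed
    one; the summation is done in exact integer arithmetic.  Returns
    (odds ratio, p).  An empty margin gives p = 1 and odds ratio NaN.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        odds = math.nan
        return odds, 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    w_obs = weights[a - lo]
    p = sum(w for w in weights if w <= w_obs) / total
    odds = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else (a * d) / (b * c)
    )
    return odds, float(p)


def positional_bias(
    cluster_profile: MotifCountProfile,
    background_profile: MotifCountProfile,
    split: int = 750,
    L: int = 1500,
) -> PositionalBiasResult:
    """Fisher exact test for motif bias toward the TSS-proximal promoter end.

    Positions are 0-based from the promoter 5' end, so "proximal" means a
    match start at or beyond L - split (the ``split`` bases nearest the
    TSS).  Occurrences are pooled over genes within each profile.
    """

    def split_counts(profile: MotifCountProfile) -> tuple[int, int]:
        prox = dist = 0
        for m in profile.per_gene.values():
            for pos in m.positions:
                if pos >= L - split:
                    prox += 1
                else:
                    dist += 1
        return prox, dist

    cp, cd = split_counts(cluster_profile)
    bp, bd = split_counts(background_profile)
    table = ((cp, cd), (bp, bd))
    odds, p = fisher_exact_two_sided(table)
    degenerate = math.isnan(odds)
    return PositionalBiasResult(table=table, odds_ratio=odds, p=p, degenerate=degenerate)


def _welch(means_a: np.ndarray, means_b: np.ndarray) -> tuple[float, float, bool]:
    """Welch t and two-sided p for two equal-or-unequal-size samples."""
    na, nb = len(means_a), len(means_b)
    ma, mb = means_a.mean(), means_b.mean()
    va, vb = means_a.var(ddof=1), means_b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, True
        return math.copysign(math.inf, diff), 0.0, True
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return float(t), p, False


def pobo_enrichment(
    cluster_genes,
    promoters,
    background,
    motif: MotifSpec,
    B: int = 1000,
    seed: int = 0,
    cluster_id: int | str = "cluster",
    _cluster_counts: dict[str, int] | None = None,
    _background_counts: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Pseudocluster bootstrap enrichment of a motif in a gene cluster.

    B pseudoclusters of size n (the usable cluster size) are drawn with
    replacement from the cluster genes and another B from the background
    gene pool; the Welch t compares the two collections of pseudocluster
    mean counts.  Genes without a promoter are excluded (logged).  Both
    resampling streams are seeded identically, so a cluster identical to
    the background pool yields t = 0 exactly, and swapping the two roles
    under the same seed negates t exactly.
    """
    usable = [g for g in cluster_genes if g in promoters]
    skipped = len(list(cluster_genes)) - len(usable)
    if skipped:
        logger.info("pobo_enrichment: %d cluster gene(s) without promoter excluded", skipped)
    n = len(usable)
    if n < 3:
        raise ValueError(f"need >= 3 cluster genes with promoters, got {n}")
    bg_genes = background.gene_ids
    if _cluster_counts is None:
        _cluster_counts = {g: count_motif(promoters[g], motif).count for g in usable}
    if _background_counts is None:
        _background_counts = {g: count_motif(background[g], motif).count for g in bg_genes}
    counts_c = np.array([_cluster_counts[g] for g in usable], dtype=float)
    counts_b = np.array([_background_counts[g] for g in bg_genes], dtype=float)

    rng_c = np.random.default_rng(seed)
    rng_b = np.random.default_rng(seed)
    means_c = counts_c[rng_c.integers(0, n, size=(B, n))].mean(axis=1)
    means_b = counts_b[rng_b.integers(0, len(counts_b), size=(B, n))].mean(axis=1)
    t, p, degenerate = _welch(means_c, means_b)
    if degenerate:
        logger.warning("pobo_enrichment: zero-variance pseudocluster means (motif %s)", motif.name)
        if not math.isfinite(t):
            t = 0.0
            p = 1.0
    return EnrichmentResult(
        motif_name=motif.name,
        cluster_id=cluster_id,
        n=n,
        B=B,
        mean_cluster=float(counts_c.mean()),
        mean_background=float(counts_b.mean()),
        t_value=t,
        p_two_sided=p,
        seed=seed,
        degenerate=degenerate,
    )


def count_level_t(cluster_genes, promoters, background, motif: MotifSpec) -> tuple[float, float]:
    """Calibrated alternative to the pseudocluster bootstrap: Welch t on the
    raw per-promoter motif counts, cluster vs background, with no
    resampling.  Its null distribution is an ordinary t, so p-values are
    interpretable at face value — use it as a sanity check on bootstrap
    results.  Returns (t, two-sided p)."""
    usable = [g for g in cluster_genes if g in promoters]
    counts_c = np.array([count_motif(promoters[g], motif).count for g in usable], dtype=float)
    counts_b = np.array(
        [count_motif(background[g], motif).count for g in background.gene_ids], dtype=float
    )
    t, p, degenerate = _welch(counts_c, counts_b)
    if degenerate and not math.isfinite(t):
        return 0.0, 1.0
    return t, p


def motif_panel(
    clusters,
    probe_map,
    promoters,
    background,
    motifs,
    B: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """One enrichment result per (cluster, motif).

    Pseudocluster seeds are derived deterministically as ``seed + index``
    over the (cluster, motif) grid; per-gene counting is cached per motif.
    Per-cell failures (e.g. too few promoters) are logged and skipped
    rather than aborting the panel.
    """
    from .io import map_cluster_to_genes

    results: list[EnrichmentResult] = []
    # per-motif count caches: every promoter counted once per motif
    cluster_cache: dict[str, dict[str, int]] = {}
    bg_cache: dict[str, dict[str, int]] = {}
    for motif in motifs:
        cluster_cache[motif.name] = {
            g: count_motif(promoters[g], motif).count for g in promoters.gene_ids
        }
        bg_cache[motif.name] = {
            g: count_motif(background[g], motif).count for g in background.gene_ids
        }
    index = 0
    for cluster in clusters:
        members = sorted(cluster.members)
        genes, _ = map_cluster_to_genes(members, probe_map)
        for motif in motifs:
            try:
                results.append(
                    pobo_enrichment(
                        genes,
                        promoters,
                        background,
                        motif,
                        B=B,
                        seed=seed + index,
                        cluster_id=cluster.cluster_id,
                        _cluster_counts=cluster_cache[motif.name],
                        _background_counts=bg_cache[motif.name],
                    )
                )
            except ValueError as exc:
                logger.warning(
                    "motif_panel: cluster %s x motif %s skipped (%s)",
                    cluster.cluster_id,
                    motif.name,
                    exc,
                )
            index += 1
    return results


def panel_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "motif": r.motif_name,
                "n": r.n,
                "B": r.B,
                "mean_cluster": r.mean_cluster,
                "mean_background": r.mean_background,
                "t_value": r.t_value,
                "p_two_sided": r.p_two_sided,
                "seed": r.seed,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
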