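"""Motif scanning, Fisher exact positional bias, pseudocluster bootstrap."""

import math
from fractions import Fraction

import numpy as np
import pytest

from regulonkit.io import PromoterSet
from regulonkit.motifs import (
    MotifCountProfile,
    MotifMatches,
    MotifSpec,
    count_level_t,
    count_motif,
    fisher_exact_two_sided,
    motif_panel,
    panel_to_frame,
    pobo_enrichment,
    positional_bias,
)


class TestCountMotif:
    def test_emsa_oligomer_contains_core_motif_once(self):
        m = count_motif("GAAATTTTGG", MotifSpec("GAAATT", "GAAATT"))
        assert (m.count, m.positions) == (1, [0])

    def test_overlapping_matches_all_counted(self):
        m = count_motif("AAAAA", MotifSpec("AAA", "AAA"))
        assert m.count == 3
        assert m.positions == [0, 1, 2]

    def test_seven_n_gap_dyad(self):
        # CCT + 7 arbitrary bases + TCC
        spec = MotifSpec("dyad", "CCTNNNNNNNTCC")
        assert count_motif("CCTAGAGAGATCC", spec).count == 1
        # an 8-base gap must not match the 7-N pattern
        assert count_motif("CCTAGAGAGAGTCC", spec).count == 0

    def test_sequence_n_only_matches_pattern_n(self):
        assert count_motif("GANATT", MotifSpec("GAAATT", "GAAATT")).count == 0
        assert count_motif("GANATT", MotifSpec("GANATT", "GANATT")).count == 1

    def test_iupac_degeneracy(self):
        # W-box variants TTGACC/TTGACT via IUPAC Y
        spec = MotifSpec("wbox", "TTGACY")
        assert count_motif("TTGACC", spec).count == 1
        assert count_motif("TTGACT", spec).count == 1
        assert count_motif("TTGACA", spec).count == 0

    def test_invalid_iupac_letter_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MotifSpec("bad", "GAXATT")

    def test_both_strands_palindrome_doubles_at_same_positions(self):
        spec_sense = MotifSpec("pal", "GAATTC")
        spec_both = MotifSpec("pal", "GAATTC", strand_mode="both")
        seq = "AGAATTCTTGAATTC"
        sense = count_motif(seq, spec_sense)
        both = count_motif(seq, spec_both)
        assert both.count == 2 * sense.count
        assert both.positions == sorted(sense.positions * 2)


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_two_sided(((1, 1), (1, 1)))[1] == 1.0

    def test_diagonal_table_enumeration(self):
        # margins 2/2/2/2: three tables, p = 1/3 for the diagonal
        _, p = fisher_exact_two_sided(((2, 0), (0, 2)))
        assert p == pytest.approx(1 / 3, abs=1e-15)

    def test_empty_margin_degenerate(self):
        odds, p = fisher_exact_two_sided(((0, 0), (3, 4)))
        assert p == 1.0 and math.isnan(odds)

    def test_matches_fraction_oracle_on_random_tables(self, rng):
        """Exhaustive hypergeometric enumeration with exact rational
        arithmetic as the oracle."""
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 20, 4))
            table = ((a, b), (c, d))
            _, p = fisher_exact_two_sided(table)
            r1, r2, c1 = a + b, c + d, a + c
            if r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
                assert p == 1.0
                continue
            lo, hi = max(0, c1 - r2), min(r1, c1)
            weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
            total = sum(weights)
            obs = weights[a - lo]
            oracle = Fraction(sum(w for w in weights if w <= obs), total)
            assert abs(p - float(oracle)) < 1e-12

    def test_agrees_with_scipy(self, rng):
        from scipy import stats

        for _ in range(200):
            table = rng.integers(0, 30, (2, 2))
            _, p = fisher_exact_two_sided(tuple(map(tuple, table.tolist())))
            assert p == pytest.approx(stats.fisher_exact(table)[1], abs=1e-9)


def profile_from_positions(positions_by_gene, motif=None):
    motif = motif or MotifSpec("GAAATT", "GAAATT")
    return MotifCountProfile(
        motif=motif,
        per_gene={
            g: MotifMatches(count=len(pos), positions=list(pos), strands=["+"] * len(pos))
            for g, pos in positions_by_gene.items()
        },
    )


class TestPositionalBias:
    def test_proximal_means_nearest_tss(self):
        # L=1500, split=750: positions >= 750 are TSS-proximal
        cluster = profile_from_positions({"g1": [800, 1400], "g2": [100]})
        background = profile_from_positions({"b1": [10, 900]})
        res = positional_bias(cluster, background)
        assert res.table == ((2, 1), (1, 1))

    def test_row_and_column_swap_invariance(self, rng):
        cluster = profile_from_positions({"g1": list(rng.integers(0, 1500, 8))})
        background = profile_from_positions({"b1": list(rng.integers(0, 1500, 25))})
        res = positional_bias(cluster, background)
        # swap roles and the proximal/distal sense simultaneously
        flipped = positional_bias(background, cluster, split=750, L=1500)
        (a, b), (c, d) = res.table
        assert flipped.table == ((c, d), (a, b))
        swapped_both = fisher_exact_two_sided(((d, c), (b, a)))[1]
        assert res.p == pytest.approx(swapped_both, abs=1e-15)

    def test_planted_proximal_bias_detected(self, rng):
        cluster = profile_from_positions({"g": [int(v) for v in rng.integers(800, 1490, 20)]})
        background = profile_from_positions({"b": [int(v) for v in rng.integers(0, 1490, 400)]})
        res = positional_bias(cluster, background)
        assert res.p < 0.01
        assert res.odds_ratio > 1


def uniform_promoters(rng, genes, mean, L=600):
    """Promoters of pure C background with a Poisson number of planted
    GAAATT instances at disjoint slots."""
    seqs = {}
    slots = L // 10
    for g in genes:
        k = min(rng.poisson(mean), slots)
        starts = rng.choice(slots, size=k, replace=False) * 10
        s = bytearray(b"C" * L)
        for st in starts:
            s[st : st + 6] = b"GAAATT"
        seqs[g] = s.decode()
    return PromoterSet(sequences=seqs, length=L)


class TestPoboEnrichment:
    MOTIF = MotifSpec("GAAATT", "GAAATT")

    def test_same_seed_bit_identical(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(50)], 2.0)
        cl = uniform_promoters(rng, [f"g{i}" for i in range(8)], 6.0)
        r1 = pobo_enrichment(cl.gene_ids, cl, bg, self.MOTIF, B=200, seed=3)
        r2 = pobo_enrichment(cl.gene_ids, cl, bg, self.MOTIF, B=200, seed=3)
        assert (r1.t_value, r1.p_two_sided) == (r2.t_value, r2.p_two_sided)

    def test_identical_pools_paired_seed_t_exactly_zero(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(30)], 2.0)
        res = pobo_enrichment(bg.gene_ids, bg, bg, self.MOTIF, B=100, seed=11)
        assert res.t_value == 0.0
        assert res.p_two_sided == 1.0

    def test_role_swap_negates_t(self, rng):
        # equal-size pools: the paired seed streams make the swap exact
        bg = uniform_promoters(rng, [f"b{i}" for i in range(10)], 2.0)
        cl = uniform_promoters(rng, [f"g{i}" for i in range(10)], 6.0)
        fwd = pobo_enrichment(cl.gene_ids, cl, bg, self.MOTIF, B=150, seed=5)
        rev = pobo_enrichment(bg.gene_ids, bg, cl, self.MOTIF, B=150, seed=5)
        assert rev.t_value == pytest.approx(-fwd.t_value, abs=1e-9)
        # unequal pools: pseudocluster size follows the cluster, so only the
        # sign is guaranteed, up to resampling noise
        bg2 = uniform_promoters(rng, [f"c{i}" for i in range(40)], 2.0)
        fwd2 = pobo_enrichment(cl.gene_ids, cl, bg2, self.MOTIF, B=150, seed=5)
        rev2 = pobo_enrichment(bg2.gene_ids, bg2, cl, self.MOTIF, B=150, seed=5)
        assert fwd2.t_value > 0 > rev2.t_value

    def test_sign_tracks_mean_difference(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(60)], 2.0)
        cl = uniform_promoters(rng, [f"g{i}" for i in range(12)], 6.0)
        res = pobo_enrichment(cl.gene_ids, cl, bg, self.MOTIF, B=200, seed=1)
        assert math.copysign(1, res.t_value) == math.copysign(
            1, res.mean_cluster - res.mean_background
        )

    def test_planted_enrichment_detected(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(300)], 2.0)
        cl = uniform_promoters(rng, [f"g{i}" for i in range(30)], 6.0)
        res = pobo_enrichment(cl.gene_ids, cl, bg, self.MOTIF, B=1000, seed=9)
        assert res.t_value > 0
        assert res.p_two_sided < 1e-4

    def test_motif_absent_everywhere_degenerate(self):
        seqs = {f"g{i}": "C" * 100 for i in range(10)}
        proms = PromoterSet(sequences=seqs, length=100)
        res = pobo_enrichment(proms.gene_ids, proms, proms, self.MOTIF, B=50, seed=0)
        assert res.degenerate
        assert res.t_value == 0.0 and res.p_two_sided == 1.0

    def test_too_few_genes_is_an_error(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(10)], 2.0)
        with pytest.raises(ValueError):
            pobo_enrichment(["b0", "b1"], bg, bg, self.MOTIF)

    def test_count_level_t_is_calibrated_helper(self, rng):
        bg = uniform_promoters(rng, [f"b{i}" for i in range(400)], 2.0)
        cluster = list(rng.choice(bg.gene_ids, size=12, replace=False))
        t, p = count_level_t(cluster, bg, bg, self.MOTIF)
        assert abs(t) < 4  # an ordinary t-variate under the null


class TestMotifPanel:
    def test_shape_and_determinism(self, rng):
        from regulonkit.dpclus import Cluster
        from regulonkit.io import ProbesetGeneMap

        genes = [f"AT1G{i:05d}" for i in range(12)]
        pmap = ProbesetGeneMap({f"p{i}_at": g for i, g in enumerate(genes)})
        proms = uniform_promoters(rng, genes, 3.0)
        bg = uniform_promoters(rng, [f"b{i}" for i in range(40)], 2.0)
        clusters = [
            Cluster(cluster_id=1, members=frozenset(f"p{i}_at" for i in range(6)), density=1.0),
            Cluster(cluster_id=2, members=frozenset(f"p{i}_at" for i in range(6, 12)), density=1.0),
        ]
        motifs = [MotifSpec("GAAATT", "GAAATT"), MotifSpec("AAGTC", "AAGTC"),
                  MotifSpec("dyad", "CCTNNNNNNNTCC")]
        panel = motif_panel(clusters, pmap, proms, bg, motifs, B=100, seed=42)
        assert len(panel) == 6  # 2 clusters x 3 motifs
        rerun = motif_panel(clusters, pmap, proms, bg, motifs, B=100, seed=42)
        assert panel_to_frame(panel).equals(panel_to_frame(rerun))
        # seeds fan out as seed + index over the grid
        assert [r.seed for r in panel] == [42 + i for i in range(6)]
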