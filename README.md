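# regulonkit

Guide-gene co-expression regulon analysis for transcriptomic compendia.

Transcription factors rarely announce their targets. One way to find
candidates is to start from a few *guide genes* — known pathway members
whose behaviour marks the conditions of interest — and mine a large
collection of expression experiments for genes that co-express with them.
`regulonkit` implements that workflow end to end for the salicylic-acid
defence pathway setting in *Arabidopsis thaliana* (the isochorismate
synthase gene *SID2* as target, the partially redundant regulators
*CBP60g* and *SARD1* as guides), but every stage is generic:

1. **Condition screening** — per experiment, the Spearman rank correlation
   ρ between the target probeset and each regulator probeset, with an
   exact permutation p-value for small arrays (n ≤ 9) and the
   t-approximation `t = ρ√((n−2)/(1−ρ²))` otherwise. An experiment is
   selected when any regulator reaches ρ ≥ 0.7 with p ≤ 0.05. An inverse
   mode selects experiments where a regulator is induced (treatment minus
   control ≥ 1 log2) yet uncorrelated with the target (ρ ≤ 0.5).
2. **Normalization and merging** — per experiment each probeset row is
   median-centered; the selected experiments are concatenated and each row
   scaled to sample SD 1. Rank correlations downstream are provably
   invariant to the scaling, which the tests exploit as a cross-check.
3. **Seed network expansion** — starting from a seed list of responsive
   probesets, every probeset whose maximum ρ against any seed reaches a
   cutoff (0.8 stringent, 0.7 relaxed) joins the network; edges connect
   pairs with ρ at or above the cutoff (positive correlations only).
4. **Overlapping density clustering** — a from-scratch, fully
   deterministic greedy clustering in the DPClus style: clusters grow from
   high-degree seeds under a minimum density `d = 2|E|/(k(k−1)) ≥ 0.75`
   and a cluster-property constraint
   `cp(v) = |E(v,C)|/(d(C)·|C∖{v}|) ≥ 0.75` that ejects sparsely connected
   periphery nodes; clusters may overlap.
5. **Promoter motif enrichment** — IUPAC motif scanning (overlapping
   matches, gapped dyads as runs of N, optional reverse-strand scan) over
   fixed 1500-bp upstream sequences; enrichment by the pseudocluster
   bootstrap: 1000 same-size resamples from the cluster and from a genomic
   background, compared by a Welch t on the pseudocluster means.
   Positional bias toward the transcription start site is tested by an
   exact two-sided Fisher test on proximal/distal occurrence counts
   (integer-exact hypergeometric summation).
6. **qPCR validation** — the mixed model `Cp_gytr = GYT_gyt + R_r + ε`,
   fitted by REML with the single variance ratio profiled out; expression
   relative to *Actin2* as −ΔCp; contrasts with model-based standard
   errors from the fixed-effect covariance.

A synthetic-data module generates every input with planted ground truth
(correlated/uncorrelated experiment regimes, latent-factor co-expression
modules, promoters with planted motif densities and positional bias, qPCR
data from the mixed model), so the whole pipeline is testable without any
external download.

## Worked example

```python
from regulonkit.dpclus import ClusterParams, cluster_graph
from regulonkit.network import build_network, expand_seeds
from regulonkit.normalize import median_center, merge_and_scale
from regulonkit.screen import GuideConfig, screen_experiment, select_experiments
from regulonkit.synthetic import default_truth, gen_experiment_collection

truth = default_truth(1)                       # 20 experiments, 12 correlated
_, matrices, _ = gen_experiment_collection(truth)
records = [screen_experiment(m, GuideConfig()) for m in matrices]
selected = set(select_experiments([r for r in records if r]))
merged = merge_and_scale([median_center(m) for m in matrices
                          if m.experiment_id in selected])
members = expand_seeds(merged, truth.seed_probesets(), cutoff=0.8)
net = build_network(merged, members, cutoff=0.8)
clusters = cluster_graph(net, ClusterParams(min_size=3))
```

Running `python examples/02_network_and_clusters.py` (which is exactly
this) prints:

```
merged matrix: 500 probesets x 240 arrays
seed expansion at rho >= 0.8: 30 probesets
network: 30 nodes, 135 edges
cluster 1: 10 members, density 1.00
cluster 2: 10 members, density 1.00
cluster 3: 10 members, density 1.00
```

The 12 correlated experiments are selected (240 arrays merged), the three
planted 10-probeset modules are recovered exactly as three full-density
clusters, and the target's cluster contains both regulators — the planted
regulon. `examples/03_motif_enrichment.py` then reports the planted
GAAATT enrichment in that cluster (cluster mean 6.67 vs background 2.37
motifs per promoter, bootstrap t = 139.6) and the planted TSS-proximal
bias of the CCT-n7-TCC dyad (17/22 proximal occurrences vs 343/709 in the
background, Fisher p = 0.0087); `examples/04_qpcr_mixed_model.py` fits
the mixed model and recovers the planted 2.0-log2 mutant suppression
(estimate +2.12, se 0.16, p = 5.5e-20).

The other examples cover experiment screening (`01`), the qPCR model
(`04`) and the file-based pipeline with its checksummed run manifest
(`05`). A thin CLI wraps the same functions
(`regulonkit screen|merge|network|cluster|motifs|qpcr|simulate|run-all`).

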