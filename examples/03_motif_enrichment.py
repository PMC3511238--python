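"""Bootstrap promoter-motif enrichment and positional bias.

The guide-module promoters carry the GAAATT motif (the core of the
regulator-bound GAAATTTTGG oligomer) at three times the genomic rate, and a
CCT-n7-TCC dyad biased toward the transcription start site.  The bootstrap
compares 1000 same-size pseudoclusters from the cluster and from a clean
genomic background; the positional bias is a Fisher exact test on
proximal/distal occurrence counts.
"""

from regulonkit.io import map_cluster_to_genes
from regulonkit.motifs import pobo_enrichment, positional_bias, profile_promoters
from regulonkit.synthetic import default_truth, gen_promoters

truth = default_truth(1)
promoters, background, _ = gen_promoters(truth, n_background=500)
genes, _ = map_cluster_to_genes(truth.guide_module, truth.probe_map())
print(f"cluster of {len(genes)} genes vs background of {len(background)} promoters")

for motif in (truth.motif, truth.control_motif):
    res = pobo_enrichment(genes, promoters, background, motif, B=1000, seed=1)
    print(
        f"{motif.name:>10}: cluster mean {res.mean_cluster:.2f} vs background "
        f"{res.mean_background:.2f} motifs/promoter, t = {res.t_value:.1f}, "
        f"p = {res.p_two_sided:.3g}"
    )

cl_prof = profile_promoters(promoters, truth.dyad_motif, genes)
bg_prof = profile_promoters(background, truth.dyad_motif)
bias = positional_bias(cl_prof, bg_prof, split=750, L=1500)
(a, b), (c, d) = bias.table
print(
    f"\n{truth.dyad_motif.name}: {a}/{a + b} cluster occurrences in the proximal "
    f"750 bp vs {c}/{c + d} in the background; Fisher p = {bias.p:.3g}"
)
print("\nA large positive t marks a motif over-represented in the cluster's")
print("promoters.  Note that the bootstrap inflates the effective sample")
print("size, so pseudocluster p-values are anti-conservative; judge them")
print("together with the per-promoter means.  The positional test asks")
print("whether occurrences pile up near the transcription start site.")
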