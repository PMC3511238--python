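# Methods

This note documents the models and procedures implemented in `regulonkit`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Correlation screening

Each expression experiment is scored independently by the Spearman rank
correlation between the target probeset and each regulator probeset.
Spearman ρ is computed as the Pearson correlation of mid-ranks (average
ranks for ties), which reduces to `1 − 6Σd²/(n(n²−1))` for untied data.
The rank statistic is deliberately non-parametric: the compendium mixes
experiments with very different designs and intensity distributions, and
ranks are also invariant to the median-centering/SD-scaling used later, so
screening and network construction see the same correlation structure.

The two-sided p-value uses full permutation enumeration for n ≤ 9 untied
arrays (the null distribution over all n! rank permutations, cached per
n) and otherwise the t-approximation `t = ρ√((n−2)/(1−ρ²))` on n − 2
degrees of freedom. Continuity (AS89-style) corrections are omitted; the
exact branch is preferred wherever it is feasible, and for the array
counts at which the approximation is used (n ≥ 10) its error is well
below the selection resolution. |ρ| = 1 on the approximation branch
returns p = 0 with a logged flag.

Selection is inclusive at both thresholds (ρ ≥ 0.7 **and** p ≤ 0.05, any
regulator). The inverse ("induced but uncorrelated") mode needs
treatment/control array labels; induction is the regulator's mean log2
difference between the two groups, with a default threshold of 1.0 log2 —
induction is described only qualitatively in the source setting, so 1.0
(a two-fold change) is this package's choice.

When two probesets report the same gene (as with the regulator SARD1 on
the ATH1 chip), both are screened; either can satisfy selection, and gene
level summaries collapse them via the probeset→gene map.

## Normalization and merging

Within each selected experiment every probeset row is centered to median
0 (even counts use the mean of the two central order statistics).
Experiments are then concatenated and each row is scaled to sample SD 1
(n − 1 denominator, matching R's `sd`). The probeset universe of the
merged matrix is the intersection across experiments — on a single array
platform this is a no-op, but synthetic or mixed inputs may differ, and
downstream correlation needs complete rows. Rows with SD below 1e−12 are
dropped as constant.

Neither step alters within-experiment ranks, so Spearman correlations are
exactly invariant to the scaling; the test suite asserts bit-identical
correlation matrices before and after scaling as a cross-check on both
stages. The scaling matters only for consumers of the merged values
themselves (export, visualisation).

## Seed network expansion and construction

A probeset joins the network when its maximum Spearman ρ against **any**
seed reaches the cutoff. The any-seed (max) aggregation is the design
choice here — it is the most permissive reading and keeps modules that
correlate with only part of a heterogeneous seed list; a mean-over-seeds
aggregation is available via an internal switch. Seeds are always
retained, even when they fail to correlate with anything. Edges connect
member pairs with signed ρ at or above the cutoff; negative correlations
never create edges, because the objects of interest are positively
co-expressed regulons. Membership and edges are nested in the cutoff by
construction.

## Density clustering

The clustering is a deterministic re-implementation of the
density/periphery greedy scheme used for protein networks (DPClus), with
the priority rules fixed normatively, since published versions of the
original tool differ in tie-handling detail:

* **seed**: unfinished node of highest degree, ties by lexicographic id;
* **growth**: among neighbours of the cluster, the candidate with most
  edges into the cluster (ties: higher total degree, then id) is added if
  post-addition density stays ≥ `d_min` and the candidate's cluster
  property (computed against the current cluster) stays ≥ `cp_min`;
  growth stops when no candidate qualifies;
* **periphery ejection** runs after growth stalls (not after every
  addition): the lowest-cp member is removed repeatedly until all members
  satisfy `cp_min` and the density satisfies `d_min`;
* clusters below the minimum size are discarded; in overlapping mode
  emitted members are retired as future seeds but remain available as
  growth candidates, in non-overlapping mode they leave the working graph.

For a singleton cluster the density is treated as 1 for the candidate
check, so the first neighbour always qualifies; a seed ejected from its
own cluster is still retired to guarantee termination. Defaults follow
the source analysis: `d_min = cp_min = 0.75`, minimum size 3 (stringent
network) or 5 (relaxed network), overlapping on. Exact reproduction of
the original GUI tool's cluster boundaries is not claimed; determinism
and testability were preferred over bit-fidelity.

## Promoter motifs

Motifs are fixed-length IUPAC strings; gapped dyads are written with runs
of N (CCT-n7-TCC as `CCTNNNNNNNTCC`). Matching is by compiled regular
expression with a lookahead so overlapping occurrences all count. An N in
the *sequence* matches only the pattern letter N — ambiguous bases never
satisfy a concrete pattern letter. The default scan is the upstream
sequence as written ("sense"); `strand_mode="both"` additionally scans
the reverse complement and reports those matches at forward coordinates,
which doubles counts for palindromic patterns (asserted as a property
test). Promoters are fixed 1500-bp windows upstream of the transcription
start site; shorter sequences contribute their full length, and
per-promoter statistics are per promoter, not per base.

### Pseudocluster bootstrap enrichment

For a cluster of n genes, B = 1000 pseudoclusters of size n are drawn
with replacement from the cluster genes and another B from a genomic
background pool; the statistic per pseudocluster is the mean motif count
per promoter, and the reported t is a Welch two-sample t between the two
B-sized collections of pseudocluster means (two-sided p from the t
distribution with Welch–Satterthwaite df). The original tool fits curves
to the pseudocluster frequency histograms before comparing them; the
direct t on the means is the same centre/spread comparison without the
fitting choices, and that divergence is deliberate.

**Calibration warning.** The bootstrap t is faithful to the published
scheme but strongly anti-conservative: resampling inflates the effective
sample size, so under the null (a cluster that is just a random draw from
the background) the t has standard deviation of roughly
`sqrt((1/n + 1/N)·B·n/2)` — about 22 for n = 10, B = 1000 — rather
than 1, and nominal p-values are correspondingly overstated. Results
carry B so users can judge, and `count_level_t` provides a calibrated
alternative (a plain Welch t on the raw per-promoter counts, no
resampling) for sanity-checking any enrichment call. Faithfulness was
chosen over recalibration for the default; the benchmark consequences are
spelled out under *Synthetic benchmarks* below. Both resampling streams
are seeded identically, which makes the statistic exactly antisymmetric
under role swap (for equal-size pools) and exactly zero when cluster and
background are the same multiset — properties the tests assert.

The genomic background pool does not exclude the cluster genes; with
backgrounds of hundreds to thousands of genes the overlap is immaterial,
and not excluding matches the "clean background" usage being emulated.

### Positional bias

Whether a motif's occurrences pile up near the transcription start site
is tested on a 2×2 table of pooled occurrence counts — cluster vs
background × proximal (match start within the final `split` = 750 bp of
the 1500-bp window) vs distal — with a two-sided Fisher exact test. The
p-value sums hypergeometric point probabilities not exceeding the
observed one, computed in exact integer arithmetic, so it agrees with
exhaustive enumeration to machine precision. Degenerate margins give
p = 1 with an undefined odds ratio, flagged.

## qPCR mixed model

Crossing-point values are modelled as

    Cp_gytr = GYT_gyt + R_r + ε_gytr,

with a fixed mean per gene:genotype:treatment cell, a random intercept
per biological replicate, `R ~ N(0, σ²_R)` and `ε ~ N(0, σ²_e)`. Because
the model has exactly one variance ratio λ = σ²_R/σ²_e, REML is computed
by profiling: for each λ the GLS estimates and the residual quadratic
form come from closed-form sufficient statistics (the replicate structure
inverts by Woodbury), and the restricted likelihood is maximized over λ
by bounded scalar optimization, with σ²_R floored at zero. No general
mixed-model machinery is involved; the test suite checks the fit against
an independent general-purpose REML implementation on unbalanced data.
Data with zero residual variance short-circuit to exact cell means. A
single replicate makes σ²_R unidentifiable and is rejected with an
instruction to fall back to fixed effects.

Relative expression follows the ΔCp convention at 100% amplification
efficiency (one cycle = one log2 unit): the reported quantity is
−(Cp_gene − Cp_reference) so that higher expression gives a higher value,
with the raw ΔCp also exposed; the reference is Actin2 (AT3G18780) by
default. Standard errors come from the fixed-effect covariance
(`√(v_gg + v_rr − 2v_gr)`), and contrasts between two cells use the full
quadratic form, so shared reference terms and replicate effects cancel
exactly where they should — adding a constant to one replicate's Cp
values changes no contrast (tested numerically).

Contrast t-tests use the residual REML degrees of freedom (observations
minus fitted cells). A replicates-minus-one convention was considered
and rejected: the contrast SE is driven by σ̂²_e, whose precision is the
residual df, and simulation shows the residual-df test holds its nominal
size (type-I error ≈ 0.05 in a ±3σ binomial band over 2000 null fits)
where the replicates-based df would reject at well under 1%. Satterthwaite
approximation is unnecessary here because the contrasts of interest are
free of the replicate variance component.

## Synthetic data

The generator produces every input with planted ground truth, emulating
the statistical structure the analysis assumes rather than the raw
technology:

* **Experiments.** Each module has one latent activity per array;
  members are `loading·a + noise`. Guides are coupled to the guide
  module's latent in "correlated" experiments (loading 1.0, noise SD 0.2,
  giving expected Spearman ≈ 0.95) and fully decoupled in "uncorrelated"
  ones, where the first regulator instead gains a +2.0 log2 treatment
  offset (the abiotic-stress pattern for the inverse selection mode).
  Defaults: 20 experiments (12 correlated), 20 arrays each, 3 modules of
  10 probesets among 500, member noise SD 0.3, i.i.d. N(8, 1) elsewhere.
  Twenty arrays is a middling real experiment size and keeps the null
  tail P(|ρ| > 0.5) below 3%, so the decoupled regime is cleanly below
  the inverse-selection cap; at very small array counts (n ≈ 10) the
  Spearman null has SD 1/3 and no generator can keep pure-noise
  correlations reliably under 0.5.
* **Promoters.** Uniform ACGT sequence with a Poisson number of motif
  instances planted at non-overlapping positions: mean 2.0 per 1500-bp
  background promoter (a realistic genomic density for a 6-mer of this
  composition) and 3× that in guide-module promoters; a CCT-n7-TCC dyad
  is planted with 80% TSS-proximal placement in guide-module promoters
  and uniformly in the background. Planted counts are a lower bound on
  recounts — chance matches can only add. A uniform background is
  adequate for planted-recovery testing; it does not reproduce the
  dinucleotide structure of real promoters, so absolute chance-match
  rates in real genomes will differ (a higher-order Markov background
  would be the natural extension).
* **qPCR.** Cp drawn exactly from the mixed model: σ_R = 0.3, σ_e = 0.2
  cycles, 5 replicates, a stable reference at Cp 15, targets induced
  −4 cycles by treatment with +2 cycles (i.e. 2.0 log2 suppression) in
  the mutant.

Everything is reproducible from one master seed; per-section streams are
spawned as `default_rng([master_seed, section, index])`, and the pipeline
fans a master seed out to stages by a documented counter scheme.

### Synthetic benchmarks: what passing shows

The end-to-end benchmark (20 master seeds) demonstrates that, under the
planted conditions, experiment selection returns exactly the correlated
experiments, the guide module is recovered as a single cluster containing
the target and both regulator probesets, and the planted 3× motif signal
is detected at p < 0.001 — all at ≥ 95% of seeds. It does **not**
demonstrate performance on real compendia (no batch effects, no
platform-specific noise, no correlated backgrounds), and it deliberately
exposes the bootstrap's mis-calibration: an *unplanted* control motif
frequently reports nominally significant enrichment, because of the
resampling inflation described above. That behaviour is a property of
the published enrichment scheme, reproduced here by design; treat small
bootstrap p-values as a ranking signal, confirm with `count_level_t`, and
weigh the per-promoter means.

## Numerical choices

* Thresholds are inclusive; floating-point comparisons against cutoffs
  use a 1e−12 slack on the inclusive side.
* All orderings are total and deterministic (lexicographic tie-breaks in
  seeding, growth, ejection, ranking and export), so identical inputs
  give byte-identical outputs.
* Fisher exact p-values are computed in integer arithmetic; Spearman
  exact p-values from cached integer Σd² distributions.
* Expression I/O writes 10 significant digits; round-trips preserve ids
  exactly and values to that precision.
* Probesets containing NA within an experiment are dropped from that
  experiment on read (with a logged count), so correlation code never
  sees missing values; constant rows are dropped at merge with reason.

## Known limitations

* The clustering is a normative reconstruction, not a bit-exact clone of
  any particular release of the original GUI tool.
* Bootstrap enrichment p-values are anti-conservative (see above).
* The exact Spearman branch requires untied data; tied small-n inputs
  fall back to the t-approximation.
* Promoter truncation keeps the 3′ (TSS-proximal) end; whether upstream
  sequence overlapping a neighbouring gene should be clipped is left to
  the input preparation, not decided here.
* The mixed model fits a single random intercept; gene-specific replicate
  effects or technical-replicate nesting are out of scope (technical
  duplicates are averaged upstream).
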