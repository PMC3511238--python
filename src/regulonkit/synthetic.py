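"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a collection of expression experiments in which guide probesets (one
  target, several candidate regulators) are either tightly co-expressed
  through a shared latent activity ("correlated" experiments) or decoupled
  from it ("uncorrelated" experiments, where the first regulator is instead
  induced by treatment — the abiotic-stress pattern);
* co-expressed modules driven by one latent factor per module per array,
  with i.i.d. noise probesets around them;
* promoters with a motif planted at a Poisson per-promoter rate, elevated
  by a multiplier in module genes, plus a gapped dyad planted with a
  proximal positional bias in guide-module promoters;
* qPCR Cp data following the random-replicate-intercept model.

Everything is reproducible from a single master seed; per-experiment and
per-section streams are spawned through ``numpy.random.default_rng`` seeded
with [master_seed, section, index] so stages stay independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExperimentManifest,
    ExpressionMatrix,
    ManifestRecord,
    ProbesetGeneMap,
    PromoterSet,
    SeedSet,
    write_expression_matrix,
    write_promoter_fasta,
)
from .motifs import MotifSpec, IUPAC_CLASSES
from .qpcr import QpcrDataset, REFERENCE_GENE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TARGET_PROBESET = "262177_at"
REGULATOR_PROBESETS = [
    ("CBP60g", "246821_at"),
    ("SARD1_a", "260046_at"),
    ("SARD1_b", "260068_at"),
]
GUIDE_GENES = {
    "262177_at": "AT1G74710",
    "246821_at": "AT5G26920",
    "260046_at": "AT1G73805",
    "260068_at": "AT1G73805",  # two probesets report the same gene
}


@dataclass
class SyntheticTruth:
    """Planted parameters from which every synthetic input derives."""

    master_seed: int
    n_probesets: int = 500
    n_experiments: int = 20
    n_correlated: int = 12
    n_arrays: int = 20
    n_modules: int = 3
    module_size: int = 10
    loading: float = 1.0
    member_noise_sd: float = 0.3
    guide_noise_sd: float = 0.2
    baseline: float = 8.0
    noise_sd: float = 1.0
    induction_log2: float = 2.0
    promoter_length: int = 1500
    background_motif_mean: float = 2.0
    module_motif_multiplier: float = 3.0
    dyad_background_mean: float = 1.0
    dyad_cluster_mean: float = 2.0
    dyad_proximal_fraction: float = 0.8
    qpcr_sigma_R: float = 0.3
    qpcr_sigma_e: float = 0.2
    qpcr_n_replicates: int = 5
    motif: MotifSpec = field(default_factory=lambda: MotifSpec("GAAATT", "GAAATT"))
    control_motif: MotifSpec = field(default_factory=lambda: MotifSpec("AAGTC", "AAGTC"))
    dyad_motif: MotifSpec = field(
        default_factory=lambda: MotifSpec("CCT_n7_TCC", "CCTNNNNNNNTCC")
    )
    probeset_ids: list[str] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    regimes: list[str] = field(default_factory=list)
    gene_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.probeset_ids:
            self._build_universe()

    def _build_universe(self) -> None:
        if not 0 <= self.n_correlated <= self.n_experiments:
            raise ValueError("n_correlated must be between 0 and n_experiments")
        guide_ids = [TARGET_PROBESET] + [p for _, p in REGULATOR_PROBESETS]
        n_filler = self.n_probesets - len(guide_ids)
        filler = [f"s{i:05d}_at" for i in range(n_filler)]
        # guide module: target + regulators + filler to module_size
        k = self.module_size - len(guide_ids)
        modules = {"module_guide": guide_ids + filler[:k]}
        used = k
        for m in range(1, self.n_modules):
            modules[f"module_{m}"] = filler[used : used + self.module_size]
            used += self.module_size
        self.modules = modules
        self.probeset_ids = guide_ids + filler
        self.regimes = ["correlated"] * self.n_correlated + ["uncorrelated"] * (
            self.n_experiments - self.n_correlated
        )
        gene_map = dict(GUIDE_GENES)
        for i, p in enumerate(filler):
            gene_map[p] = f"AT2G{10000 + i * 10:05d}"
        self.gene_map = gene_map

    # --- derived conveniences -------------------------------------------
    @property
    def guide_module(self) -> list[str]:
        return self.modules["module_guide"]

    def probe_map(self) -> ProbesetGeneMap:
        return ProbesetGeneMap(mapping=dict(self.gene_map))

    def module_genes(self, module_id: str) -> list[str]:
        seen, genes = set(), []
        for p in self.modules[module_id]:
            g = self.gene_map[p]
            if g not in seen:
                seen.add(g)
                genes.append(g)
        return genes

    def seed_probesets(self, per_module: int = 4) -> SeedSet:
        """Planted analog of the differentially expressed seed list: a few
        members of each module, guide target included, regulators not."""
        regulators = {p for _, p in REGULATOR_PROBESETS}
        ids: list[str] = []
        for module in self.modules.values():
            picked = [p for p in module if p not in regulators][:per_module]
            ids.extend(picked)
        return SeedSet(ids)

    def correlated_experiment_ids(self) -> list[str]:
        return [
            f"exp{i:03d}" for i, r in enumerate(self.regimes) if r == "correlated"
        ]


def default_truth(master_seed: int, **overrides) -> SyntheticTruth:
    return SyntheticTruth(master_seed=master_seed, **overrides)


# ---------------------------------------------------------------------------
# expression experiments
# ---------------------------------------------------------------------------

def gen_experiment_collection(
    truth: SyntheticTruth,
) -> tuple[ExperimentManifest, list[ExpressionMatrix], dict[str, str]]:
    """Generate all experiments plus array group labels.

    Returns (manifest, matrices, array_groups) where array_groups maps
    array ids to "treatment"/"control" (the array id carries the label as a
    ctrl_/trt_ prefix as well).  Manifest paths are filled in only by
    :func:`write_collection`.
    """
    matrices = []
    records = []
    array_groups: dict[str, str] = {}
    guide_ids = [TARGET_PROBESET] + [p for _, p in REGULATOR_PROBESETS]
    idx = {p: i for i, p in enumerate(truth.probeset_ids)}
    n_arr = truth.n_arrays
    half = n_arr // 2
    array_ids = [f"ctrl_{j:02d}" for j in range(half)] + [
        f"trt_{j:02d}" for j in range(n_arr - half)
    ]
    for a in array_ids:
        array_groups[a] = "control" if a.startswith("ctrl_") else "treatment"
    trt_mask = np.array([a.startswith("trt_") for a in array_ids])

    for e, regime in enumerate(truth.regimes):
        rng = np.random.default_rng([truth.master_seed, 1, e])
        values = truth.baseline + rng.normal(0.0, truth.noise_sd, (truth.n_probesets, n_arr))
        for module_id, members in truth.modules.items():
            latent = rng.normal(0.0, 1.0, n_arr)
            for p in members:
                if p in guide_ids:
                    continue  # guides handled per regime below
                values[idx[p]] = truth.baseline + truth.loading * latent + rng.normal(
                    0.0, truth.member_noise_sd, n_arr
                )
            if module_id == "module_guide":
                if regime == "correlated":
                    for p in guide_ids:
                        values[idx[p]] = (
                            truth.baseline
                            + truth.loading * latent
                            + rng.normal(0.0, truth.guide_noise_sd, n_arr)
                        )
                else:
                    # decoupled guides; first regulator induced by treatment
                    for p in guide_ids:
                        values[idx[p]] = truth.baseline + rng.normal(0.0, truth.noise_sd, n_arr)
                    first_reg = REGULATOR_PROBESETS[0][1]
                    values[idx[first_reg]] += truth.induction_log2 * trt_mask
        exp_id = f"exp{e:03d}"
        matrices.append(
            ExpressionMatrix(
                experiment_id=exp_id,
                probeset_ids=list(truth.probeset_ids),
                array_ids=list(array_ids),
                values=values,
            )
        )
        records.append(
            ManifestRecord(
                experiment_id=exp_id,
                path=Path(f"{exp_id}.tsv"),
                n_arrays=n_arr,
                treatment="biotic" if regime == "correlated" else "abiotic",
            )
        )
    return ExperimentManifest(records), matrices, array_groups


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, L: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, L)].tobytes())


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Replace degenerate IUPAC letters with concrete bases."""
    out = []
    for c in pattern:
        if c in "ACGT":
            out.append(c)
        else:
            opts = "ACGT" if c == "N" else IUPAC_CLASSES[c]
            out.append(opts[rng.integers(0, len(opts))])
    return "".join(out)


def _plant(
    seq: bytearray,
    pattern: str,
    k: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    region: tuple[int, int] | None = None,
    max_tries: int = 200,
) -> list[int]:
    """Place k non-overlapping concrete instances of the motif; returns
    start positions.  Raises RuntimeError when placement keeps failing."""
    L = len(seq)
    m = len(pattern)
    lo, hi = region if region is not None else (0, L - m)
    hi = min(hi, L - m)
    placed = []
    for _ in range(k):
        inst = _instantiate(pattern, rng)
        for _try in range(max_tries):
            start = int(rng.integers(lo, hi + 1))
            if all(start + m <= s or start >= s + w for s, w in occupied):
                seq[start : start + m] = inst.encode()
                occupied.append((start, m))
                placed.append(start)
                break
        else:
            raise RuntimeError("motif placement failed after bounded retries")
    return placed


def gen_promoters(
    truth: SyntheticTruth,
    n_background: int = 500,
) -> tuple[PromoterSet, PromoterSet, dict[str, dict[str, list[int]]]]:
    """Promoters for the gene universe plus a separate genomic background.

    The primary motif is planted Poisson(background mean) per background
    promoter and Poisson(multiplier x mean) in guide-module promoters; the
    gapped dyad is planted with a TSS-proximal bias in guide-module
    promoters and uniformly in the background.  Returns (universe
    promoters, background promoters, truth positions per motif per gene).
    Chance matches in the random sequence can only add to the planted
    counts, never remove them.
    """
    L = truth.promoter_length
    rng = np.random.default_rng([truth.master_seed, 2])
    module_gene_sets = {
        mid: set(truth.module_genes(mid)) for mid in truth.modules
    }
    guide_genes = module_gene_sets["module_guide"]
    universe_genes = []
    seen = set()
    for p in truth.probeset_ids:
        g = truth.gene_map[p]
        if g not in seen:
            seen.add(g)
            universe_genes.append(g)
    bg_genes = [f"AT3G{10000 + i * 10:05d}" for i in range(n_background)]

    planted: dict[str, dict[str, list[int]]] = {
        truth.motif.name: {},
        truth.dyad_motif.name: {},
    }
    prox_region = (L - 750, L)  # TSS-proximal half
    dist_region = (0, L - 751)

    def make(gene: str, in_guide_module: bool) -> str:
        seq = _random_seq(rng, L)
        occupied: list[tuple[int, int]] = []
        mean = truth.background_motif_mean
        if in_guide_module:
            mean *= truth.module_motif_multiplier
        k = int(rng.poisson(mean))
        planted[truth.motif.name][gene] = _plant(seq, truth.motif.pattern, k, rng, occupied)
        dyad_mean = truth.dyad_cluster_mean if in_guide_module else truth.dyad_background_mean
        kd = int(rng.poisson(dyad_mean))
        pos = []
        for _ in range(kd):
            if in_guide_module:
                proximal = rng.random() < truth.dyad_proximal_fraction
            else:
                proximal = rng.random() < 0.5
            region = prox_region if proximal else dist_region
            pos += _plant(seq, truth.dyad_motif.pattern, 1, rng, occupied, region=region)
        planted[truth.dyad_motif.name][gene] = pos
        return seq.decode()

    universe = {g: make(g, g in guide_genes) for g in universe_genes}
    background = {g: make(g, False) for g in bg_genes}
    return (
        PromoterSet(sequences=universe, length=L),
        PromoterSet(sequences=background, length=L),
        planted,
    )


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def default_gyt(
    genes: list[str],
    genotypes: tuple[str, ...] = ("Col0", "cbp60g_sard1"),
    treatments: tuple[str, ...] = ("mock", "Pma"),
) -> dict[tuple[str, str, str], float]:
    """Planted cell means: a stable reference gene, pathogen-induced target
    genes (lower Cp = higher expression), induction suppressed in the
    mutant."""
    gyt: dict[tuple[str, str, str], float] = {}
    for y in genotypes:
        for t in treatments:
            gyt[(REFERENCE_GENE, y, t)] = 15.0
    for i, g in enumerate(genes):
        if g == REFERENCE_GENE:
            continue
        base = 26.0 + 0.5 * i
        for y in genotypes:
            for t in treatments:
                cp = base
                if t != treatments[0]:
                    cp -= 4.0  # induction
                    if y != genotypes[0]:
                        cp += 2.0  # suppressed in the mutant
                gyt[(g, y, t)] = cp
    return gyt


def gen_qpcr(
    truth: SyntheticTruth,
    genes: list[str] | None = None,
    genotypes: tuple[str, ...] = ("Col0", "cbp60g_sard1"),
    treatments: tuple[str, ...] = ("mock", "Pma"),
    n_replicates: int | None = None,
    gyt: dict[tuple[str, str, str], float] | None = None,
) -> tuple[QpcrDataset, dict[tuple[str, str, str], float]]:
    """Cp = GYT + R_r + eps with R_r ~ N(0, sigma_R), eps ~ N(0, sigma_e).

    The reference gene is always included.  Returns the dataset and the
    planted GYT means."""
    rng = np.random.default_rng([truth.master_seed, 3])
    if genes is None:
        genes = [REFERENCE_GENE] + [truth.gene_map[p] for p in truth.guide_module[:4]]
        genes = list(dict.fromkeys(genes))
    elif REFERENCE_GENE not in genes:
        genes = [REFERENCE_GENE] + list(genes)
    reps = n_replicates if n_replicates is not None else truth.qpcr_n_replicates
    if gyt is None:
        gyt = default_gyt([g for g in genes if g != REFERENCE_GENE], genotypes, treatments)
    rep_effects = rng.normal(0.0, truth.qpcr_sigma_R, reps)
    rows = []
    for g in genes:
        for y in genotypes:
            for t in treatments:
                for r in range(reps):
                    cp = gyt[(g, y, t)] + rep_effects[r] + rng.normal(0.0, truth.qpcr_sigma_e)
                    rows.append(
                        {"gene": g, "genotype": y, "treatment": t,
                         "replicate": f"rep{r + 1}", "cp": cp}
                    )
    return QpcrDataset(pd.DataFrame(rows)), gyt


# ---------------------------------------------------------------------------
# writing a full input directory
# ---------------------------------------------------------------------------

def write_collection(truth: SyntheticTruth, outdir, n_background: int = 500) -> dict[str, Path]:
    """Write every pipeline input to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest, matrices, _ = gen_experiment_collection(truth)
    paths: dict[str, Path] = {}
    for record, matrix in zip(manifest.records, matrices):
        p = outdir / f"{matrix.experiment_id}.tsv"
        write_expression_matrix(matrix, p)
        record.path = p
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("experiment_id\tfile\tn_arrays\ttreatment\n")
        for r in manifest.records:
            fh.write(f"{r.experiment_id}\t{r.path.name}\t{r.n_arrays}\t{r.treatment}\n")
    paths["manifest"] = manifest_path

    seeds = truth.seed_probesets()
    seeds_path = outdir / "seeds.txt"
    with open(seeds_path, "w") as fh:
        fh.write("# seed probesets (planted module members)\n")
        for s in seeds:
            fh.write(s + "\n")
    paths["seeds"] = seeds_path

    map_path = outdir / "probe_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("# probeset_id\tgene_id\n")
        for p, g in truth.gene_map.items():
            fh.write(f"{p}\t{g}\n")
    paths["probe_map"] = map_path

    promoters, background, _ = gen_promoters(truth, n_background=n_background)
    prom_path = outdir / "promoters.fasta"
    bg_path = outdir / "background.fasta"
    write_promoter_fasta(promoters, prom_path)
    write_promoter_fasta(background, bg_path)
    paths["promoters"] = prom_path
    paths["background"] = bg_path

    motifs_path = outdir / "motifs.tsv"
    with open(motifs_path, "w") as fh:
        fh.write("name\tpattern\tstrand_mode\n")
        for m in (truth.motif, truth.control_motif, truth.dyad_motif):
            fh.write(f"{m.name}\t{m.pattern}\t{m.strand_mode}\n")
    paths["motifs"] = motifs_path

    qpcr_data, gyt = gen_qpcr(truth)
    cp_path = outdir / "cp.tsv"
    qpcr_data.data.to_csv(cp_path, sep="\t", index=False)
    paths["qpcr"] = cp_path

    truth_path = outdir / "truth.json"
    serializable = asdict(truth)
    for key in ("motif", "control_motif", "dyad_motif"):
        serializable[key] = serializable[key]["pattern"]
    serializable["qpcr_gyt"] = {"|".join(k): v for k, v in gyt.items()}
    with open(truth_path, "w") as fh:
        json.dump(serializable, fh, indent=1)
    paths["truth"] = truth_path
    return paths
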