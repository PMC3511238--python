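"""End-to-end orchestration: screen -> merge -> network -> cluster -> motifs
(-> qpcr), with uniform logging, per-stage seeds and a checksummed run
manifest so identical configs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dpclus import ClusterParams, cluster_graph
from .io import (
    read_expression_matrix,
    read_manifest,
    read_probe_map,
    read_promoter_fasta,
    read_seed_list,
    map_cluster_to_genes,
)
from .motifs import MotifSpec, motif_panel, panel_to_frame
from .network import CoexpressionNetwork, build_network, expand_seeds
from .normalize import median_center, merge_and_scale, write_merged_matrix
from .qpcr import REFERENCE_GENE, fit_mixed, read_qpcr_table, relative_expression
from .screen import GuideConfig, screen_experiment, select_experiments

logger = logging.getLogger(__name__)

STAGES = ["screen", "merge", "network", "cluster", "motifs", "qpcr"]


@dataclass
class PipelineConfig:
    manifest: Path
    seeds: Path
    promoters: Path
    background: Path
    motifs: Path
    probe_map: Path
    outdir: Path
    qpcr: Path | None = None
    guide: GuideConfig = field(default_factory=GuideConfig)
    expansion_cutoff: float = 0.8
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    pseudo_count: int = 1000
    master_seed: int = 0
    reference_gene: str = REFERENCE_GENE

    def __post_init__(self) -> None:
        for name in ("manifest", "seeds", "promoters", "background", "motifs", "probe_map"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"config: {name} file {p} does not exist")
        if self.qpcr is not None:
            self.qpcr = Path(self.qpcr)
            if not self.qpcr.exists():
                raise FileNotFoundError(f"config: qpcr file {self.qpcr} does not exist")
        if not 0.0 < self.expansion_cutoff <= 1.0:
            raise ValueError("expansion_cutoff must be in (0, 1]")
        self.outdir = Path(self.outdir)


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config.  Relative paths resolve against the
    config file's directory."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    guide_raw = raw.get("guide", {})
    guide = GuideConfig(
        target=guide_raw.get("target", GuideConfig().target),
        regulators=[tuple(r) for r in guide_raw.get("regulators", GuideConfig().regulators)],
        rho_min=float(guide_raw.get("rho_min", 0.7)),
        p_max=float(guide_raw.get("p_max", 0.05)),
    )
    cl_raw = raw.get("cluster", {})
    cluster_params = ClusterParams(
        d_min=float(cl_raw.get("d_min", 0.75)),
        cp_min=float(cl_raw.get("cp_min", 0.75)),
        min_size=int(cl_raw.get("min_size", 3)),
        overlapping=bool(cl_raw.get("overlapping", True)),
    )
    return PipelineConfig(
        manifest=resolve(raw["manifest"]),
        seeds=resolve(raw["seeds"]),
        promoters=resolve(raw["promoters"]),
        background=resolve(raw["background"]),
        motifs=resolve(raw["motifs"]),
        probe_map=resolve(raw["probe_map"]),
        qpcr=resolve(raw["qpcr"]) if raw.get("qpcr") else None,
        outdir=resolve(raw.get("outdir", "out")),
        guide=guide,
        expansion_cutoff=float(raw.get("expansion_cutoff", 0.8)),
        cluster_params=cluster_params,
        pseudo_count=int(raw.get("pseudo_count", 1000)),
        master_seed=int(raw.get("master_seed", 0)),
        reference_gene=raw.get("reference_gene", REFERENCE_GENE),
    )


def read_motif_table(path) -> list[MotifSpec]:
    motifs = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, pattern = parts[0], parts[1]
            strand = parts[2] if len(parts) > 2 else "sense"
            motifs.append(MotifSpec(name, pattern, strand))
    return motifs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    # documented counter scheme: master*100 + stage index, one slot per stage
    return master_seed * 100 + STAGES.index(stage)


def export_network(net: CoexpressionNetwork, clusters, fmt: str, path) -> None:
    """Write the network for external viewers.

    ``sif``: one line "A co B" per edge; ``tsv``: edge list with weights;
    ``gml``: nodes carry cluster membership, edges carry weight.  Output
    ordering is stable (sorted ids), so re-export is byte-identical.
    """
    path = Path(path)
    edges = sorted(net.edges.items())
    if fmt == "sif":
        with open(path, "w") as fh:
            for (a, b), _ in edges:
                fh.write(f"{a} co {b}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for (a, b), w in edges:
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
    elif fmt == "gml":
        membership: dict[str, list[int]] = {n: [] for n in net.nodes}
        for cl in clusters or []:
            for m in cl.members:
                membership[m].append(cl.cluster_id)
        node_index = {n: i for i, n in enumerate(sorted(net.nodes))}
        with open(path, "w") as fh:
            fh.write("graph [\n")
            for n in sorted(net.nodes):
                cl_str = ",".join(str(c) for c in sorted(membership[n]))
                fh.write(
                    f'  node [\n    id {node_index[n]}\n    label "{n}"\n'
                    f'    clusters "{cl_str}"\n  ]\n'
                )
            for (a, b), w in edges:
                fh.write(
                    f"  edge [\n    source {node_index[a]}\n    target {node_index[b]}\n"
                    f"    weight {w:.10g}\n  ]\n"
                )
            fh.write("]\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the run manifest (also written to
    outdir/run_manifest.json).  Any stage error aborts with the stage name
    while retaining partial outputs."""
    outdir = config.outdir
    manifest: dict = {"version": __version__, "master_seed": config.master_seed, "stages": []}
    stage = "setup"
    try:
        experiments = read_manifest(config.manifest)
        probe_map = read_probe_map(config.probe_map)
        seeds = read_seed_list(config.seeds)
        promoters = read_promoter_fasta(config.promoters)
        background = read_promoter_fasta(config.background)
        motifs = read_motif_table(config.motifs)

        # --- screen ---
        stage = "screen"
        sdir = outdir / "screen"
        sdir.mkdir(parents=True, exist_ok=True)
        records = []
        matrices = {}
        for rec in experiments:
            m = read_expression_matrix(rec.path, rec.experiment_id)
            matrices[rec.experiment_id] = m
            r = screen_experiment(m, config.guide)
            if r is not None:
                records.append(r)
        screen_path = sdir / "screen.tsv"
        with open(screen_path, "w") as fh:
            names = [n for n, _ in config.guide.regulators]
            fh.write(
                "experiment_id\tn_arrays\t"
                + "\t".join(f"rho_{n}\tp_{n}" for n in names)
                + "\tselected\n"
            )
            for r in records:
                cells = []
                for n in names:
                    s = r.stats.get(n)
                    cells.append("NA\tNA" if s is None else f"{s.rho:.6g}\t{s.p:.6g}")
                fh.write(f"{r.experiment_id}\t{r.n_arrays}\t" + "\t".join(cells) + f"\t{int(r.selected)}\n")
        selected = select_experiments(records, "target_correlated")
        _log_stage(manifest, stage, {"n_experiments": len(records), "n_selected": len(selected)}, [screen_path], config)

        # --- merge ---
        stage = "merge"
        mdir = outdir / "merged"
        mdir.mkdir(parents=True, exist_ok=True)
        centered = [median_center(matrices[e]) for e in selected]
        merged = merge_and_scale(centered)
        merged_path = mdir / "merged.tsv"
        write_merged_matrix(merged, merged_path)
        dropped_path = mdir / "dropped.tsv"
        with open(dropped_path, "w") as fh:
            fh.write("probeset_id\treason\n")
            for pid, reason in merged.dropped_probesets:
                fh.write(f"{pid}\t{reason}\n")
        _log_stage(
            manifest, stage,
            {"n_probesets": len(merged.probeset_ids), "n_arrays": merged.n_arrays},
            [merged_path, dropped_path], config,
        )

        # --- network ---
        stage = "network"
        ndir = outdir / "network"
        ndir.mkdir(parents=True, exist_ok=True)
        members = expand_seeds(merged, seeds, config.expansion_cutoff)
        net = build_network(
            merged, members, config.expansion_cutoff,
            seed_flags={m: m in set(seeds) for m in members},
        )
        sif_path = ndir / "edges.sif"
        tsv_path = ndir / "edges.tsv"
        export_network(net, [], "sif", sif_path)
        export_network(net, [], "tsv", tsv_path)
        _log_stage(manifest, stage, {"n_nodes": len(net.nodes), "n_edges": len(net.edges)}, [sif_path, tsv_path], config)

        # --- cluster ---
        stage = "cluster"
        cdir = outdir / "clusters"
        cdir.mkdir(parents=True, exist_ok=True)
        clusters = cluster_graph(net, config.cluster_params)
        clusters_path = cdir / "clusters.tsv"
        with open(clusters_path, "w") as fh:
            fh.write("cluster_id\tprobeset_id\tgene_id\tdensity\tcp\n")
            for cl in clusters:
                for m in sorted(cl.members):
                    gene = probe_map.mapping.get(m, "NA")
                    fh.write(f"{cl.cluster_id}\t{m}\t{gene}\t{cl.density:.6g}\t{cl.cp[m]:.6g}\n")
        gml_path = cdir / "network.gml"
        export_network(net, clusters, "gml", gml_path)
        _log_stage(manifest, stage, {"n_clusters": len(clusters)}, [clusters_path, gml_path], config)

        # --- motifs ---
        stage = "motifs"
        modir = outdir / "motifs"
        modir.mkdir(parents=True, exist_ok=True)
        panel = motif_panel(
            clusters, probe_map, promoters, background, motifs,
            B=config.pseudo_count, seed=_stage_seed(config.master_seed, "motifs"),
        )
        panel_path = modir / "enrichment.tsv"
        panel_to_frame(panel).to_csv(panel_path, sep="\t", index=False)
        _log_stage(manifest, stage, {"n_results": len(panel)}, [panel_path], config)

        # --- qpcr (optional) ---
        if config.qpcr is not None:
            stage = "qpcr"
            qdir = outdir / "qpcr"
            qdir.mkdir(parents=True, exist_ok=True)
            data = read_qpcr_table(config.qpcr)
            fit = fit_mixed(data)
            rel = relative_expression(fit, config.reference_gene)
            rel_path = qdir / "rel.tsv"
            with open(rel_path, "w") as fh:
                fh.write("genotype\ttreatment\tgene\trel_log2\tdelta_cp\tse\n")
                for (y, t), genes in sorted(rel.rel.items()):
                    for g in sorted(genes):
                        fh.write(
                            f"{y}\t{t}\t{g}\t{rel.rel[(y, t)][g]:.6g}\t"
                            f"{rel.delta_cp[(y, t)][g]:.6g}\t{rel.se[(y, t)][g]:.6g}\n"
                        )
            _log_stage(
                manifest, stage,
                {"sigma2_R": float(fit.sigma2_R), "sigma2_e": float(fit.sigma2_e),
                 "n_cells": len(fit.cells)},
                [rel_path], config,
            )
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        raise RuntimeError(f"pipeline aborted in stage {stage!r}") from None

    manifest_path = outdir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _log_stage(manifest: dict, stage: str, params: dict, outputs: list[Path], config: PipelineConfig) -> None:
    entry = {
        "stage": stage,
        "seed": _stage_seed(config.master_seed, stage) if stage in STAGES else None,
        "params": params,
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    logger.info("stage %s: %s", stage, params)
    manifest["stages"].append(entry)
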