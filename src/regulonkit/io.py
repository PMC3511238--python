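"""Readers, writers and validators for the pipeline's file formats.

All tabular inputs are plain TSV ('.' decimal, no quoting, '#' comments where
noted); promoters are FASTA.  Expression matrices are log2 intensities with
probesets as rows and arrays as columns — the post-normalization product of a
standard microarray preprocessing chain, which is out of scope here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Arabidopsis AGI locus code, e.g. AT1G74710 (chromosomes 1-5, C, M).
AGI_PATTERN = re.compile(r"^AT[1-5CM]G\d{5}$")


class DataError(ValueError):
    """Unusable input: malformed file, duplicate ids, bad values."""


@dataclass
class ExpressionMatrix:
    """One experiment's log2 expression values, probesets x arrays."""

    experiment_id: str
    probeset_ids: list[str]
    array_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probeset_ids), len(self.array_ids)):
            raise DataError(
                f"{self.experiment_id}: value matrix shape {self.values.shape} does "
                f"not match {len(self.probeset_ids)} probesets x "
                f"{len(self.array_ids)} arrays"
            )
        dupes = _duplicates(self.probeset_ids)
        if dupes:
            raise DataError(f"{self.experiment_id}: duplicate probeset ids {dupes}")
        dupes = _duplicates(self.array_ids)
        if dupes:
            raise DataError(f"{self.experiment_id}: duplicate array ids {dupes}")
        if len(self.array_ids) < 2:
            raise DataError(
                f"{self.experiment_id}: needs >=2 arrays, got {len(self.array_ids)}"
            )

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def row(self, probeset_id: str) -> np.ndarray:
        return self.values[self.probeset_ids.index(probeset_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probeset_ids, columns=self.array_ids)


@dataclass
class ManifestRecord:
    experiment_id: str
    path: Path
    n_arrays: int
    treatment: str


@dataclass
class ExperimentManifest:
    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        dupes = _duplicates([r.experiment_id for r in self.records])
        if dupes:
            raise DataError(f"manifest: duplicate experiment ids {dupes}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, experiment_id: str) -> ManifestRecord:
        for r in self.records:
            if r.experiment_id == experiment_id:
                return r
        raise KeyError(experiment_id)


@dataclass
class ProbesetGeneMap:
    """Total probeset -> gene (AGI) mapping; many probesets may share a gene."""

    mapping: dict[str, str]
    malformed: list[str] = field(default_factory=list)

    def __getitem__(self, probeset_id: str) -> str:
        return self.mapping[probeset_id]

    def __contains__(self, probeset_id: str) -> bool:
        return probeset_id in self.mapping


@dataclass
class PromoterSet:
    """Upstream sequences keyed by gene id; nominal length L, shorter allowed."""

    sequences: dict[str, str]
    length: int = 1500

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class SeedSet:
    probeset_ids: list[str]

    def __post_init__(self) -> None:
        if not self.probeset_ids:
            raise DataError("seed set is empty")
        dupes = _duplicates(self.probeset_ids)
        if dupes:
            raise DataError(f"duplicate seed probesets {dupes}")

    def __iter__(self):
        return iter(self.probeset_ids)

    def __len__(self) -> int:
        return len(self.probeset_ids)


class MappedGenes(NamedTuple):
    genes: list[str]
    unmapped: list[str]


def _duplicates(items) -> list:
    seen: set = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_expression_matrix(path, experiment_id: str) -> ExpressionMatrix:
    """Read one experiment's probesets x arrays TSV.

    The header row carries array ids (first cell ignored); the first column
    carries probeset ids.  The token ``NA`` is tolerated: any probeset row
    containing it is dropped from this experiment (with a logged count) so
    that correlation code downstream never sees missing values.  Any other
    non-numeric cell is an error with row/column context.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    if df.shape[1] < 2:
        raise DataError(f"{path}: fewer than 2 arrays in header")
    array_ids = [str(c) for c in df.columns]
    probeset_ids = [str(i) for i in df.index]
    dupes = _duplicates(probeset_ids)
    if dupes:
        raise DataError(f"{path}: duplicate probeset ids {dupes}")
    raw = df.to_numpy()
    na_mask = (raw == "NA") | pd.isna(raw)
    numeric = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        ok = ~na_mask[:, j]
        try:
            numeric[ok, j] = col[ok].astype(float)
        except ValueError:
            for i in np.where(ok)[0]:
                try:
                    float(col[i])
                except ValueError:
                    raise DataError(
                        f"{path}: non-numeric value {col[i]!r} at probeset "
                        f"{probeset_ids[i]}, array {array_ids[j]}"
                    ) from None
    keep = ~na_mask.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d probeset(s) containing NA", experiment_id, n_dropped
        )
    return ExpressionMatrix(
        experiment_id=experiment_id,
        probeset_ids=[p for p, k in zip(probeset_ids, keep) if k],
        array_ids=array_ids,
        values=numeric[keep],
    )


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write TSV readable by :func:`read_expression_matrix` (10 sig. digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("probeset_id\t" + "\t".join(m.array_ids) + "\n")
        for pid, row in zip(m.probeset_ids, m.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_manifest(path) -> ExperimentManifest:
    """Read the experiment manifest TSV.

    Columns: experiment_id, file, n_arrays, treatment.  File paths are
    resolved relative to the manifest's directory and must exist.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"experiment_id", "file", "n_arrays", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise DataError(f"{path}: referenced file {p} does not exist")
        records.append(
            ManifestRecord(
                experiment_id=row["experiment_id"],
                path=p,
                n_arrays=int(row["n_arrays"]),
                treatment=row["treatment"],
            )
        )
    return ExperimentManifest(records)


def read_probe_map(path) -> ProbesetGeneMap:
    """Read probeset -> gene TSV (two columns).  Gene ids uppercased;
    ids not matching the AGI pattern are kept but flagged."""
    path = Path(path)
    mapping: dict[str, str] = {}
    malformed: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}: malformed map line {line!r}")
            probeset, gene = parts[0], parts[1].upper()
            if probeset in mapping:
                raise DataError(f"{path}: duplicate probeset {probeset}")
            if not AGI_PATTERN.match(gene):
                malformed.append(gene)
            mapping[probeset] = gene
    if malformed:
        logger.warning("%s: %d gene id(s) not AGI-formed", path, len(malformed))
    return ProbesetGeneMap(mapping=mapping, malformed=malformed)


def read_seed_list(path) -> SeedSet:
    """Read the seed probeset list: one id per line, '#' comments."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return SeedSet(ids)


def read_promoter_fasta(path, L: int = 1500) -> PromoterSet:
    """Read promoters from FASTA, one record per gene.

    Record id = token up to first whitespace, uppercased.  Sequences are
    uppercased; records longer than L are truncated to the L bases nearest
    the 3' end (the TSS-proximal side) with a warning.  Records containing
    characters outside ACGTN are rejected with a warning.  Duplicate gene
    ids are an error; an empty file is an error.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        gene_id = record.id.upper()
        seq = str(record.seq).upper()
        if gene_id in sequences:
            raise DataError(f"{path}: duplicate gene id {gene_id}")
        if set(seq) - set("ACGTN"):
            logger.warning("%s: record %s has non-ACGTN characters; skipped", path, gene_id)
            continue
        if len(seq) > L:
            logger.warning("%s: record %s longer than %d; truncated to 3' end", path, gene_id, L)
            seq = seq[-L:]
        elif len(seq) < L:
            logger.info("%s: record %s shorter than %d (kept)", path, gene_id, L)
        sequences[gene_id] = seq
    if n_records == 0:
        raise DataError(f"{path}: empty FASTA")
    return PromoterSet(sequences=sequences, length=L)


def write_promoter_fasta(promoters: PromoterSet, path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in promoters.sequences.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def map_cluster_to_genes(members, probe_map: ProbesetGeneMap) -> MappedGenes:
    """Collapse probeset members to a de-duplicated, first-occurrence-ordered
    gene list.  Several probesets reporting one gene (a real occurrence on
    the ATH1 chip) yield a single entry.  Unmapped probesets go to a side
    report rather than raising."""
    genes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for probeset in members:
        if probeset not in probe_map:
            unmapped.append(probeset)
            continue
        gene = probe_map[probeset]
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
    if unmapped:
        logger.info("map_cluster_to_genes: %d unmapped probeset(s)", len(unmapped))
    return MappedGenes(genes=genes, unmapped=unmapped)
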