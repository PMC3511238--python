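"""Two-step normalization and merge of selected experiments.

Within each experiment every probeset row is centered so its median is 0;
the per-experiment blocks are then concatenated and each probeset row is
scaled so that its sample standard deviation (n-1 denominator, matching R's
``sd``) across all arrays is 1.  Rank-based correlation downstream is
invariant to the scaling step; the merged matrix is still produced in this
form for inspection and export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-12  # rows with sample SD below this are dropped as constant


@dataclass
class MergedMatrix:
    """Cross-experiment matrix; array ids are globally unique as
    ``experiment_id:array_id`` and provenance maps them back."""

    probeset_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    provenance: dict[str, str]
    dropped_probesets: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def row(self, probeset_id: str) -> np.ndarray:
        return self.values[self.probeset_ids.index(probeset_id)]

    def experiment_blocks(self) -> dict[str, list[int]]:
        blocks: dict[str, list[int]] = {}
        for j, a in enumerate(self.array_ids):
            blocks.setdefault(self.provenance[a], []).append(j)
        return blocks


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center every probeset row at median 0 (even counts use the mean of
    the two central order statistics).  Idempotent."""
    med = np.median(m.values, axis=1, keepdims=True)
    return ExpressionMatrix(
        experiment_id=m.experiment_id,
        probeset_ids=list(m.probeset_ids),
        array_ids=list(m.array_ids),
        values=m.values - med,
    )


def merge_and_scale(matrices: list[ExpressionMatrix]) -> MergedMatrix:
    """Concatenate median-centered experiments and scale each probeset row
    to sample SD 1 across all arrays.

    The probeset universe is the intersection across experiments (row order
    follows the first experiment).  Rows with SD below ``SD_FLOOR`` are
    moved to ``dropped_probesets`` with reason "constant".  Duplicate
    global array ids or an empty intersection are errors.
    """
    if not matrices:
        raise DataError("no matrices to merge")
    common = set(matrices[0].probeset_ids)
    for m in matrices[1:]:
        common &= set(m.probeset_ids)
    if not common:
        raise DataError("empty probeset intersection across experiments")
    probesets = [p for p in matrices[0].probeset_ids if p in common]

    array_ids: list[str] = []
    provenance: dict[str, str] = {}
    blocks = []
    for m in matrices:
        idx = [m.probeset_ids.index(p) for p in probesets]
        blocks.append(m.values[idx])
        for a in m.array_ids:
            gid = f"{m.experiment_id}:{a}"
            if gid in provenance:
                raise DataError(f"duplicate global array id {gid}")
            provenance[gid] = m.experiment_id
            array_ids.append(gid)
    values = np.concatenate(blocks, axis=1)

    sd = values.std(axis=1, ddof=1)
    keep = sd >= SD_FLOOR
    dropped = [(p, "constant") for p, k in zip(probesets, keep) if not k]
    if dropped:
        logger.info("merge_and_scale: dropped %d constant probeset(s)", len(dropped))
    values = values[keep] / sd[keep, None]
    return MergedMatrix(
        probeset_ids=[p for p, k in zip(probesets, keep) if k],
        array_ids=array_ids,
        values=values,
        provenance=provenance,
        dropped_probesets=dropped,
    )


def write_merged_matrix(merged: MergedMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("probeset_id\t" + "\t".join(merged.array_ids) + "\n")
        for pid, row in zip(merged.probeset_ids, merged.values):
            fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
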