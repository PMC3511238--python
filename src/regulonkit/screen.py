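"""Per-experiment guide-gene correlation screening.

A guide configuration names a target transcript (the pathway output, e.g. the
isochorismate synthase probeset) and one or more candidate regulators.  Each
expression experiment is scored by the Spearman rank correlation between the
target and each regulator; an experiment is selected when any regulator shows
a strong, significant positive correlation.  A genome-wide correlation
ranking against the target is also provided for interrogating individual
genes across the merged, selected compendium.

The Spearman p-value is exact (full permutation enumeration) for n <= 9 with
untied data, and uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on
n-2 degrees of freedom otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_P_MAX_N = 9  # full enumeration of n! rank permutations up to here


class ConstantInputError(ValueError):
    """Correlation undefined: one of the vectors is constant."""


@dataclass
class GuideConfig:
    """Target/regulator probesets and the selection thresholds."""

    target: str = "262177_at"
    regulators: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("CBP60g", "246821_at"),
            ("SARD1_a", "260046_at"),
            ("SARD1_b", "260068_at"),
        ]
    )
    rho_min: float = 0.7
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_min <= 1.0:
            raise ValueError("rho_min must be in [0, 1]")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        if self.target in {p for _, p in self.regulators}:
            raise ValueError("target probeset cannot also be a regulator")


@dataclass
class RegulatorStat:
    rho: float
    p: float


@dataclass
class ScreenRecord:
    """One experiment's screening result.

    ``stats`` maps regulator name to its (rho, p), or None when the
    regulator probeset was absent or constant in this experiment.
    ``induction`` maps regulator name to its treatment-vs-control mean log2
    difference when array group labels were available.
    """

    experiment_id: str
    n_arrays: int
    stats: dict[str, RegulatorStat | None]
    selected: bool
    induction: dict[str, float | None] = field(default_factory=dict)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks; for untied data this equals the classical
    1 - 6*sum(d^2)/(n*(n^2-1)).  Raises :class:`ConstantInputError` when
    either vector is constant (the caller decides how to treat the
    experiment) and ValueError for length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


@lru_cache(maxsize=None)
def _exact_null_distribution(n: int) -> tuple[tuple[float, ...], tuple[int, ...]]:
    """Null distribution of rho over all n! permutations of untied ranks.

    Returns (rho values, counts), keyed by the integer statistic
    S = sum d^2, since rho = 1 - 6S/(n(n^2-1)) when there are no ties.
    """
    base = tuple(range(n))
    counts: Counter[int] = Counter()
    for perm in itertools.permutations(base):
        s = sum((i - p) ** 2 for i, p in zip(base, perm))
        counts[s] += 1
    denom = n * (n * n - 1)
    rhos = tuple(1.0 - 6.0 * s / denom for s in sorted(counts))
    cnts = tuple(counts[s] for s in sorted(counts))
    return rhos, cnts


def spearman_p(rho: float, n: int, ties: bool = False) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    Exact permutation enumeration for n <= 9 without ties; otherwise the
    t approximation on n-2 degrees of freedom.  |rho| = 1 on the
    approximation branch returns 0.0 (logged as degenerate).
    """
    if n < 4:
        raise ValueError("need n >= 4 for a meaningful p-value")
    if abs(rho) > 1 + 1e-12:
        raise ValueError("|rho| must be <= 1")
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= EXACT_P_MAX_N and not ties:
        rhos, counts = _exact_null_distribution(n)
        total = math.factorial(n)
        hits = sum(
            c for r, c in zip(rhos, counts) if abs(r) >= abs(rho) - 1e-12
        )
        return hits / total
    if abs(rho) >= 1.0:
        logger.warning("spearman_p: |rho|=1 on approximation branch; p=0 returned")
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _has_ties(v: np.ndarray) -> bool:
    return len(np.unique(v)) < len(v)


def screen_experiment(matrix, config: GuideConfig, array_groups: dict[str, str] | None = None) -> ScreenRecord | None:
    """Correlate the target against each regulator within one experiment.

    Returns None (with a log entry) when the target probeset is absent or
    constant.  An absent or constant regulator is recorded as missing and
    selection is decided on the remaining regulators.  When ``array_groups``
    maps array ids to "treatment"/"control", each regulator's mean log2
    induction (treatment minus control) is recorded as well.
    """
    if config.target not in matrix.probeset_ids:
        logger.info("%s: target %s absent; experiment skipped", matrix.experiment_id, config.target)
        return None
    target = matrix.row(config.target)
    if np.ptp(target) == 0:
        logger.info("%s: target %s constant; experiment skipped", matrix.experiment_id, config.target)
        return None
    n = matrix.n_arrays
    results: dict[str, RegulatorStat | None] = {}
    induction: dict[str, float | None] = {}
    trt = ctrl = None
    if array_groups is not None:
        trt = [i for i, a in enumerate(matrix.array_ids) if array_groups.get(a) == "treatment"]
        ctrl = [i for i, a in enumerate(matrix.array_ids) if array_groups.get(a) == "control"]
    for name, probeset in config.regulators:
        if probeset not in matrix.probeset_ids:
            results[name] = None
            induction[name] = None
            continue
        reg = matrix.row(probeset)
        try:
            rho = spearman_rho(target, reg)
        except ConstantInputError:
            results[name] = None
            induction[name] = None
            continue
        ties = _has_ties(target) or _has_ties(reg)
        results[name] = RegulatorStat(rho=rho, p=spearman_p(rho, n, ties=ties))
        if trt and ctrl:
            induction[name] = float(reg[trt].mean() - reg[ctrl].mean())
        else:
            induction[name] = None
    selected = any(
        s is not None and s.rho >= config.rho_min and s.p <= config.p_max
        for s in results.values()
    )
    return ScreenRecord(
        experiment_id=matrix.experiment_id,
        n_arrays=n,
        stats=results,
        selected=selected,
        induction=induction,
    )


def select_experiments(
    records: list[ScreenRecord],
    mode: str = "target_correlated",
    regulator: str | None = None,
    induction_min: float = 1.0,
    rho_max: float = 0.5,
) -> list[str]:
    """Pick experiments for network construction.

    ``target_correlated``: experiments whose screening record is selected
    (any regulator with rho >= rho_min and p <= p_max; thresholds
    inclusive).  ``induced_uncorrelated``: the abiotic-style selection —
    experiments where the designated regulator's treatment-vs-control mean
    log2 difference is at least ``induction_min`` while its correlation
    with the target is at most ``rho_max``.
    """
    if not records:
        raise ValueError("no screening records supplied")
    if mode == "target_correlated":
        return [r.experiment_id for r in records if r.selected]
    if mode == "induced_uncorrelated":
        if regulator is None:
            raise ValueError("induced_uncorrelated mode needs a designated regulator")
        out = []
        for r in records:
            ind = r.induction.get(regulator)
            if ind is None:
                raise ValueError(
                    f"{r.experiment_id}: no treatment/control labels; cannot "
                    "compute induction for induced_uncorrelated mode"
                )
            stat = r.stats.get(regulator)
            rho = stat.rho if stat is not None else 0.0
            if ind >= induction_min and rho <= rho_max:
                out.append(r.experiment_id)
        return out
    raise ValueError(f"unknown selection mode {mode!r}")


def rank_coexpression(merged, target: str, query: str) -> tuple[int, float]:
    """Rank a query probeset among all probesets by Spearman rho with the
    target across all merged arrays.

    The target itself is excluded from the ranking; probesets are sorted by
    rho descending with ties broken lexicographically by probeset id (the
    tie policy is logged).  Constant probesets have undefined correlation:
    a constant query is an error; other constant probesets are excluded.
    Returns (1-based rank, rho of query).
    """
    ids = merged.probeset_ids
    if target not in ids or query not in ids:
        raise KeyError("target and query must both be present in the merged matrix")
    values = merged.values
    t_idx = ids.index(target)
    t_rank = stats.rankdata(values[t_idx])
    if np.ptp(t_rank) == 0:
        raise ConstantInputError("target is constant across merged arrays")
    ranks = stats.rankdata(values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    tc = t_rank - t_rank.mean()
    tn = math.sqrt(tc @ tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ tc) / (norms * tn)
    if norms[ids.index(query)] == 0:
        raise ConstantInputError(f"query {query} is constant across merged arrays")
    order = sorted(
        (i for i in range(len(ids)) if i != t_idx and norms[i] > 0),
        key=lambda i: (-rho[i], ids[i]),
    )
    logger.debug("rank_coexpression: ties broken by lexicographic probeset id")
    q_idx = ids.index(query)
    return order.index(q_idx) + 1, float(rho[q_idx])
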