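"""Random-intercept mixed model for qPCR crossing-point (Cp) data.

The model is Cp_gytr = GYT_gyt + R_r + eps_gytr: a fixed mean per
gene:genotype:treatment cell, a random intercept per biological replicate,
and a residual.  Variance components are estimated by REML — the model has
exactly one variance ratio, so the restricted likelihood is profiled and
maximized directly over lambda = sigma2_R / sigma2_e rather than through
general mixed-model machinery.  Fixed effects are then the GLS estimates
under the fitted components, with their covariance matrix retained for
contrast standard errors.

Relative expression follows the delta-Cp convention at 100% amplification
efficiency (1 cycle = 1 log2 unit): rel = -(Cp_gene - Cp_reference), so
higher expression gives a higher value; the raw delta Cp is also exposed.
Contrast t-tests use the residual REML degrees of freedom (observations
minus fitted cells).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

REFERENCE_GENE = "AT3G18780"  # Actin2

Cell = tuple[str, str, str]  # (gene, genotype, treatment)


@dataclass
class QpcrDataset:
    """Long-format Cp records; one row per (gene, genotype, treatment,
    replicate), each Cp being the mean of technical duplicates computed
    upstream."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "genotype", "treatment", "replicate", "cp"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns {sorted(missing)}")
        keys = self.data[["gene", "genotype", "treatment", "replicate"]]
        if keys.duplicated().any():
            dupes = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate qPCR record for {dupes}")
        self.data = self.data.copy()
        self.data["cp"] = self.data["cp"].astype(float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class QpcrFit:
    cells: list[Cell]
    estimates: dict[Cell, float]
    sigma2_R: float
    sigma2_e: float
    vcov: np.ndarray
    n_reps: int
    df_resid: int
    lambda_: float

    def cell_index(self, cell: Cell) -> int:
        return self.cells.index(cell)


@dataclass
class RelativeExpression:
    fit: QpcrFit
    reference_gene: str
    rel: dict[tuple[str, str], dict[str, float]]  # (genotype, treatment) -> gene -> -dCp
    delta_cp: dict[tuple[str, str], dict[str, float]]
    se: dict[tuple[str, str], dict[str, float]]
    missing_reference: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: int
    p: float


def read_qpcr_table(path) -> QpcrDataset:
    df = pd.read_csv(path, sep="\t", comment="#")
    return QpcrDataset(df)


def _design(data: pd.DataFrame):
    cells = sorted(set(zip(data["gene"], data["genotype"], data["treatment"])))
    reps = sorted(set(data["replicate"]))
    cell_idx = {c: i for i, c in enumerate(cells)}
    rep_idx = {r: i for i, r in enumerate(reps)}
    ci = np.array([cell_idx[c] for c in zip(data["gene"], data["genotype"], data["treatment"])])
    ri = np.array([rep_idx[r] for r in data["replicate"]])
    return cells, reps, ci, ri


def fit_mixed(dataset: QpcrDataset) -> QpcrFit:
    """REML fit of the random-replicate-intercept model.

    Requires at least two replicates (one replicate leaves sigma2_R
    unidentifiable; fit the fixed-effects model instead).  sigma2_R is
    floored at 0.  In a balanced complete design the GLS fixed-effect
    estimates coincide with the cell means for any variance components.
    """
    data = dataset.data
    cells, reps, ci, ri = _design(data)
    y = data["cp"].to_numpy(dtype=float)
    n, C, R = len(y), len(cells), len(reps)
    if R < 2:
        raise ValueError(
            "only one replicate: sigma2_R is not identifiable; "
            "fit fixed effects only (cell means)"
        )
    counts = np.bincount(ci, minlength=C)
    if (counts < 1).any():
        raise ValueError("every gene:genotype:treatment cell needs >= 1 observation")

    # sufficient statistics for the profiled REML criterion
    X = np.zeros((n, C))
    X[np.arange(n), ci] = 1.0
    Z = np.zeros((n, R))
    Z[np.arange(n), ri] = 1.0
    XtX = X.T @ X
    XtZ = X.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y
    m_r = Z.sum(axis=0)
    yty = y @ y

    def profile(lam: float):
        d = lam / (1.0 + lam * m_r)
        A = XtX - (XtZ * d) @ XtZ.T
        b = Xty - XtZ @ (d * Zty)
        beta = np.linalg.solve(A, b)
        # r' V0^-1 r computed from sufficient statistics
        Ztr = Zty - XtZ.T @ beta
        rtr = yty - 2 * beta @ Xty + beta @ (XtX @ beta)
        q = rtr - Ztr @ (d * Ztr)
        return A, beta, max(q, 0.0)

    df_resid = n - C

    def neg2_reml(lam: float) -> float:
        A, _, q = profile(lam)
        if q <= 0.0:
            return -np.inf  # degenerate: perfect fit
        sigma2 = q / df_resid
        sign, logdet_A = np.linalg.slogdet(A)
        logdet_V = float(np.sum(np.log1p(lam * m_r)))
        return df_resid * math.log(sigma2) + logdet_V + logdet_A

    _, beta0, q0 = profile(0.0)
    if q0 / max(df_resid, 1) < 1e-20:
        # zero-noise degenerate data: exact cell means, zero components
        logger.info("fit_mixed: residual variance ~ 0; returning exact cell means")
        return QpcrFit(
            cells=cells,
            estimates={c: float(b) for c, b in zip(cells, beta0)},
            sigma2_R=0.0,
            sigma2_e=0.0,
            vcov=np.zeros((C, C)),
            n_reps=R,
            df_resid=df_resid,
            lambda_=0.0,
        )

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(0.0, 1e5), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    # the bounded optimizer never evaluates exactly at 0; accept the
    # boundary when it does at least as well
    if neg2_reml(0.0) <= res.fun:
        lam = 0.0
    A, beta, q = profile(lam)
    sigma2_e = q / df_resid
    sigma2_R = max(lam * sigma2_e, 0.0)
    vcov = sigma2_e * np.linalg.inv(A)
    return QpcrFit(
        cells=cells,
        estimates={c: float(b) for c, b in zip(cells, beta)},
        sigma2_R=sigma2_R,
        sigma2_e=sigma2_e,
        vcov=vcov,
        n_reps=R,
        df_resid=df_resid,
        lambda_=lam,
    )


def relative_expression(fit: QpcrFit, reference_gene: str = REFERENCE_GENE) -> RelativeExpression:
    """Reference-subtracted expression per cell.

    rel(g, y, t) = -(Cp_g,y,t - Cp_ref,y,t); the raw delta Cp is kept
    alongside.  The standard error of each rel value comes from the fitted
    covariance: sqrt(v_gg + v_rr - 2 v_gr).  Strata without a fitted
    reference cell are flagged, not fatal.
    """
    rel: dict[tuple[str, str], dict[str, float]] = {}
    dcp: dict[tuple[str, str], dict[str, float]] = {}
    se: dict[tuple[str, str], dict[str, float]] = {}
    missing: list[tuple[str, str]] = []
    strata = sorted({(y, t) for (_, y, t) in fit.cells})
    for y, t in strata:
        ref_cell = (reference_gene, y, t)
        genes = [g for (g, yy, tt) in fit.cells if (yy, tt) == (y, t)]
        if ref_cell not in fit.estimates:
            missing.append((y, t))
            logger.warning("relative_expression: no reference cell for %s/%s", y, t)
            continue
        i_ref = fit.cell_index(ref_cell)
        rel[(y, t)] = {}
        dcp[(y, t)] = {}
        se[(y, t)] = {}
        for g in genes:
            i_g = fit.cell_index((g, y, t))
            delta = fit.estimates[(g, y, t)] - fit.estimates[ref_cell]
            dcp[(y, t)][g] = delta
            rel[(y, t)][g] = -delta
            v = (
                fit.vcov[i_g, i_g]
                + fit.vcov[i_ref, i_ref]
                - 2.0 * fit.vcov[i_g, i_ref]
            )
            se[(y, t)][g] = math.sqrt(max(v, 0.0))
    return RelativeExpression(
        fit=fit,
        reference_gene=reference_gene,
        rel=rel,
        delta_cp=dcp,
        se=se,
        missing_reference=missing,
    )


def contrast(rel: RelativeExpression, a: Cell, b: Cell) -> ContrastResult:
    """Difference of relative expression between two cells, with a
    model-based standard error from the full fixed-effect covariance.

    estimate = rel_a - rel_b; the contrast vector touches the two gene
    cells and their per-stratum reference cells, so replicate effects and
    shared reference terms cancel exactly where they should.  The t-test
    uses the residual REML degrees of freedom.
    """
    fit = rel.fit
    ref = rel.reference_gene
    for cell in (a, b):
        if cell not in fit.estimates:
            raise KeyError(f"cell {cell} not fitted")
    if a == b:
        return ContrastResult(estimate=0.0, se=0.0, t=0.0, df=fit.df_resid, p=1.0)
    C = len(fit.cells)
    cvec = np.zeros(C)
    # rel_a - rel_b = -(Cp_a - Cp_ref_a) + (Cp_b - Cp_ref_b)
    cvec[fit.cell_index(a)] -= 1.0
    cvec[fit.cell_index((ref, a[1], a[2]))] += 1.0
    cvec[fit.cell_index(b)] += 1.0
    cvec[fit.cell_index((ref, b[1], b[2]))] -= 1.0
    estimate = float(cvec @ np.array([fit.estimates[c] for c in fit.cells]))
    var = float(cvec @ fit.vcov @ cvec)
    se = math.sqrt(max(var, 0.0))
    df = fit.df_resid
    if se == 0.0:
        t = 0.0 if estimate == 0.0 else math.copysign(math.inf, estimate)
        p = 1.0 if estimate == 0.0 else 0.0
    else:
        t = estimate / se
        p = float(2.0 * stats.t.sf(abs(t), df=df))
    return ContrastResult(estimate=estimate, se=se, t=t, df=df, p=p)


def profile_correlation(x, y) -> float:
    """Pearson correlation of two time-ordered log2-ratio profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("profiles must be equal-length 1-d vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
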