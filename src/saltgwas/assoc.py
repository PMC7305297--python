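"""Per-SNP association scans: fixed-effect GLM and a kinship mixed linear model.

The GLM regresses the trait on [1, dosage, PC1..PCk] by ordinary least squares
per SNP, dropping accessions with a missing dosage at that SNP.  The MLM is the
EMMAX construction: y = Xb + g*beta + u + e with u ~ N(0, sg2*K); K is
eigendecomposed once, the variance ratio delta = se2/sg2 is estimated by 1-D
REML under the null model, and every SNP is then tested by generalized least
squares at that fixed delta.  An exact mode re-optimizes delta per SNP.
Missing dosages are mean-imputed for the MLM so the rotated design stays
aligned.  Both scans are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from saltgwas.panel_io import MISSING, GenotypePanel
from saltgwas.structure import PcResult

logger = logging.getLogger(__name__)

_RESULT_COLUMNS = ["chrom", "pos", "id", "beta", "se", "p", "log10p", "maf", "n"]


@dataclass
class ModelSpec:
    """Which scan to run and with what structure correction."""

    model: str = "GLM"
    n_pcs: int = 3
    population: str = "full"
    exact: bool = False  # MLM: re-optimize delta per SNP

    def __post_init__(self) -> None:
        if self.model not in ("GLM", "MLM"):
            raise ValueError("model must be GLM or MLM")


def _covariates(n: int, pcs: PcResult | None, n_pcs: int) -> np.ndarray:
    cols = [np.ones(n)]
    if pcs is not None and n_pcs > 0:
        cols.append(pcs.scores[:, :n_pcs])
        return np.column_stack(cols)
    return np.ones((n, 1))


def _result_frame(panel: GenotypePanel, beta, se, p, maf, nused) -> pd.DataFrame:
    with np.errstate(divide="ignore"):
        log10p = -np.log10(p)
    return pd.DataFrame(
        {
            "chrom": panel.snps["chrom"].to_numpy(),
            "pos": panel.snps["pos"].to_numpy(),
            "id": panel.snps["id"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "log10p": log10p,
            "maf": maf,
            "n": nused,
        },
        columns=_RESULT_COLUMNS,
    )


def _ols_batch(G: np.ndarray, Y: np.ndarray, C: np.ndarray):
    """OLS of each column of Y on [C, g] for every complete-column g in G.

    Frisch-Waugh: residualize g and Y on C via an orthonormal basis Q, then
    simple regression.  Returns (beta, se, p) arrays of shape (m,) if Y is a
    vector, else (m, n_y).  Columns of G must have no missing entries.
    """
    n, m = G.shape
    q_c = np.linalg.qr(C, mode="reduced")[0]
    c = C.shape[1]
    Gr = G - q_c @ (q_c.T @ G)
    Yr = Y - q_c @ (q_c.T @ Y)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    df = n - c - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Gr.T @ Yr) / gg[:, None]
        yy = np.einsum("ij,ij->j", Yr, Yr)
        sse = yy[None, :] - beta**2 * gg[:, None]
        sse = np.clip(sse, 0.0, None)
        sigma2 = sse / df
        se = np.sqrt(sigma2 / gg[:, None])
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    bad = (gg <= 1e-12) | (df <= 0)
    beta[bad], se[bad], p[bad] = np.nan, np.nan, np.nan
    return beta, se, p


def _ols_single(g: np.ndarray, y: np.ndarray, C: np.ndarray):
    """OLS t-test on the dosage coefficient for one SNP with row subsetting."""
    X = np.column_stack([C, g])
    n, k = X.shape
    if n - k <= 0 or np.ptp(g) == 0:
        return np.nan, np.nan, np.nan
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return np.nan, np.nan, np.nan
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    if se == 0:
        # perfect fit: p underflows toward 0
        return coef[-1], 0.0, 0.0
    tstat = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(tstat), n - k)
    return coef[-1], se, p


def glm_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    pcs: PcResult | None = None,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Fixed-effect scan: OLS of y on [1, dosage, PCs] per SNP.

    Accessions with missing y are dropped globally; accessions with a missing
    dosage are dropped per SNP.  Monomorphic SNPs within the analysis set get
    missing p.  Returns a DataFrame with columns
    chrom, pos, id, beta, se, p, log10p, maf, n.
    """
    spec = spec or ModelSpec(model="GLM")
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    if not keep.all():
        panel = panel.subset(accessions=np.flatnonzero(keep))
        if pcs is not None:
            pcs = PcResult(pcs.scores[keep], pcs.variance_explained)
        y = y[keep]
    n, m = panel.n_accessions, panel.n_snps
    C = _covariates(n, pcs, spec.n_pcs)
    D = panel.dosages
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    nused = np.full(m, 0, dtype=int)

    has_missing = (D == MISSING).any(axis=0)
    complete = np.flatnonzero(~has_missing)
    if complete.size:
        G = D[:, complete].astype(float)
        mono = np.ptp(G, axis=0) == 0
        b, s, pv = _ols_batch(G, y[:, None], C)
        b, s, pv = b[:, 0], s[:, 0], pv[:, 0]
        b[mono], s[mono], pv[mono] = np.nan, np.nan, np.nan
        beta[complete], se[complete], p[complete] = b, s, pv
        nused[complete] = n
    n_dropped_logged = 0
    for j in np.flatnonzero(has_missing):
        ok = D[:, j] != MISSING
        g = D[ok, j].astype(float)
        beta[j], se[j], p[j] = _ols_single(g, y[ok], C[ok])
        nused[j] = int(ok.sum())
        n_dropped_logged += n - nused[j]
    if n_dropped_logged:
        logger.debug("glm_scan: dropped %d accession-calls for missing dosage", n_dropped_logged)
    return _result_frame(panel, beta, se, p, panel.maf(), nused)


# ---------------------------------------------------------------------------
# Mixed linear model (EMMAX-style)
# ---------------------------------------------------------------------------

def _reml_neg_loglik(log_delta: float, lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray) -> float:
    """Negative REML log-likelihood of delta in the rotated null model."""
    delta = np.exp(log_delta)
    w = 1.0 / (lam + delta)
    XtWX = (Xr * w[:, None]).T @ Xr
    XtWy = (Xr * w[:, None]).T @ yr
    try:
        b = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ b
    ss = float(r * w @ r)
    nq = len(yr) - Xr.shape[1]
    if ss <= 0:
        return np.inf
    sign, logdet_w = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        nq * np.log(2.0 * np.pi * ss / nq) + nq
        + np.sum(np.log(lam + delta))
        + logdet_w
    )
    return -ll


def estimate_delta(
    lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray, grid_points: int = 100
) -> float:
    """1-D REML estimate of delta = se2/sg2 over log delta in [-10, 10].

    Coarse grid then bounded scalar refinement to 1e-6.
    """
    grid = np.linspace(-10.0, 10.0, grid_points)
    vals = np.array([_reml_neg_loglik(g, lam, Xr, yr) for g in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, Xr, yr),
        method="bounded", options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def mlm_scan(
    panel: GenotypePanel,
    y: np.ndarray,
    pcs: PcResult | None,
    K: np.ndarray,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Mixed-model scan with kinship random effect (EMMAX construction).

    K is eigendecomposed once; delta is REML-estimated under the no-SNP null
    and reused for every SNP's generalized-least-squares test.  With
    ``spec.exact`` delta is re-optimized per SNP.  Non-PSD K is shifted by its
    smallest eigenvalue (with a warning).  Missing dosages are mean-imputed.
    """
    spec = spec or ModelSpec(model="MLM")
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    if not keep.all():
        panel = panel.subset(accessions=np.flatnonzero(keep))
        if pcs is not None:
            pcs = PcResult(pcs.scores[keep], pcs.variance_explained)
        K = K[np.ix_(keep, keep)]
        y = y[keep]
    n, m = panel.n_accessions, panel.n_snps
    C = _covariates(n, pcs, spec.n_pcs)

    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    if lam[0] < -1e-8:
        logger.warning("mlm_scan: kinship not PSD (min eig %.3g); shifting", lam[0])
        lam = lam - lam[0]
    lam = np.clip(lam, 0.0, None)

    yr = U.T @ y
    Cr = U.T @ C

    # mean-impute missing dosages, then rotate the whole dosage matrix at once
    D = panel.dosages.astype(float)
    miss = panel.dosages == MISSING
    if miss.any():
        p_alt = panel.allele_freq()
        D[miss] = (2.0 * p_alt)[np.nonzero(miss)[1]]
    mono = np.ptp(D, axis=0) == 0

    delta = estimate_delta(lam, Cr, yr)
    logger.debug("mlm_scan: REML delta = %.6g", delta)

    if spec.exact:
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        for j in range(m):
            if mono[j]:
                continue
            gr = U.T @ D[:, j]
            Xr = np.column_stack([Cr, gr])
            dj = estimate_delta(lam, Xr, yr)
            w = np.sqrt(1.0 / (lam + dj))
            b, s, pv = _ols_batch((gr * w)[:, None], (yr * w)[:, None], Cr * w[:, None])
            beta[j], se[j], p[j] = b[0, 0], s[0, 0], pv[0, 0]
    else:
        w = np.sqrt(1.0 / (lam + delta))
        Gr = (U.T @ D) * w[:, None]
        beta, se, p = _ols_batch(Gr, (yr * w)[:, None], Cr * w[:, None])
        beta, se, p = beta[:, 0], se[:, 0], p[:, 0]
        beta[mono], se[mono], p[mono] = np.nan, np.nan, np.nan

    return _result_frame(panel, beta, se, p, panel.maf(), np.full(m, n))


def genomic_inflation(result: pd.DataFrame) -> float:
    """Genomic inflation factor: median chi2(1) quantile of observed p / 0.4549.

    Requires >= 100 finite p-values.
    """
    p = result["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError(f"genomic_inflation needs >=100 finite p-values, got {len(p)}")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
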