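"""Significance-threshold machinery.

Three pieces:

* :func:`ld_prune_neff` — PLINK-style sliding-window LD pruning (window/step in
  SNP counts, greedy removal at r2 >= threshold) giving the effective number of
  independent markers;
* :func:`suggestive_threshold` — the -log10(1/Neff) suggestive line;
* :func:`conditional_permutation_threshold` — a structure-preserving
  permutation null: the trait is split into a PC-fitted structure component P
  and residual G, G is reshuffled across accessions, Y* = P + G_shuffled is
  rescanned, and the genome-wide minimum p over permutations yields the
  alpha-quantile threshold (the Churchill-Doerge construction conditioned on
  structure).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from saltgwas.assoc import ModelSpec, _ols_batch, _ols_single, glm_scan
from saltgwas.panel_io import MISSING, GenotypePanel
from saltgwas.structure import PcResult

logger = logging.getLogger(__name__)


@dataclass
class EffectiveSnpCount:
    """LD-pruning outcome: surviving marker count and the parameters used."""

    population: str
    window: int
    step: int
    r2_max: float
    neff: int
    kept_indices: np.ndarray = field(repr=False, default=None)


def _r2_pairwise(d: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    ok = (d[:, i] != MISSING) & (d[:, j] != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = d[ok, i].astype(float), d[ok, j].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def ld_prune_neff(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 50,
    r2_max: float = 0.2,
    population: str = "full",
) -> EffectiveSnpCount:
    """Sliding-window LD pruning to an effective independent-marker count.

    Per chromosome, a window of ``window`` SNPs advances by ``step``; within
    each window, for every pair of still-kept SNPs with r2 >= ``r2_max`` the
    later-position SNP is removed, until no such pair remains.  Neff is the
    genome-wide survivor count.
    """
    kept = np.ones(panel.n_snps, dtype=bool)
    d = panel.dosages
    for chrom, grp in panel.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            live = [j for j in win if kept[j]]
            # greedy: scan pairs in position order, drop the later member
            for a in range(len(live)):
                i = live[a]
                if not kept[i]:
                    continue
                for b in range(a + 1, len(live)):
                    j = live[b]
                    if kept[j] and _r2_pairwise(d, i, j) >= r2_max:
                        kept[j] = False
            if start + window >= len(idx):
                break
            start += step
    neff = int(kept.sum())
    logger.info("ld_prune_neff: %d/%d SNPs retained", neff, panel.n_snps)
    return EffectiveSnpCount(
        population=population, window=window, step=step, r2_max=r2_max,
        neff=neff, kept_indices=np.flatnonzero(kept),
    )


def suggestive_threshold(neff: EffectiveSnpCount | int) -> float:
    """Suggestive -log10(p) line: -log10(1/Neff) = log10(Neff)."""
    n = neff.neff if isinstance(neff, EffectiveSnpCount) else int(neff)
    if n < 1:
        raise ValueError("Neff must be >= 1")
    return float(np.log10(n))


@dataclass
class PermutationThreshold:
    """Conditional-permutation threshold report."""

    threshold: float  # -log10(p) scale
    minima: np.ndarray  # per-permutation genome-wide minimum p
    n_perm: int
    alpha: float
    seed: int
    n_pcs: int

    def to_json(self, path: str, population: str = "full", neff: int | None = None) -> None:
        report = {
            "population": population,
            "neff": neff,
            "permutation_threshold": self.threshold,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_pcs": self.n_pcs,
        }
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)


def structure_decomposition(
    y: np.ndarray, pcs: PcResult | None, n_pcs: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Split Y into the PC-fitted structure component P and residual G = Y - P."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if pcs is None or n_pcs == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), pcs.scores[:, :n_pcs]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    P = X @ coef
    return P, y - P


def min_p_scan_batch(
    panel: GenotypePanel, Y: np.ndarray, pcs: PcResult | None, n_pcs: int = 3
) -> np.ndarray:
    """Genome-wide minimum GLM p-value for each column of the phenotype matrix Y.

    Shares the per-SNP design across phenotype columns, so a thousand permuted
    scans cost little more than one.
    """
    n, m = panel.n_accessions, panel.n_snps
    n_y = Y.shape[1]
    C = np.ones((n, 1)) if (pcs is None or n_pcs == 0) else np.column_stack(
        [np.ones(n), pcs.scores[:, :n_pcs]]
    )
    D = panel.dosages
    minp = np.full(n_y, 1.0)
    has_missing = (D == MISSING).any(axis=0)
    complete = np.flatnonzero(~has_missing)
    if complete.size:
        G = D[:, complete].astype(float)
        poly = np.ptp(G, axis=0) > 0
        _, _, p = _ols_batch(G[:, poly], Y, C)
        if p.size:
            minp = np.fmin(minp, np.nanmin(p, axis=0))
    for j in np.flatnonzero(has_missing):
        ok = D[:, j] != MISSING
        g = D[ok, j].astype(float)
        if np.ptp(g) == 0:
            continue
        _, _, p = _ols_batch(g[:, None], Y[ok], C[ok])
        minp = np.fmin(minp, np.nan_to_num(p[0], nan=1.0))
    return minp


def conditional_permutation_threshold(
    panel: GenotypePanel,
    y: np.ndarray,
    pcs: PcResult | None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_pcs: int = 3,
) -> PermutationThreshold:
    """Genome-wide threshold from structure-conditional permutations.

    Y is decomposed into fitted structure P plus residual G; each permutation
    reshuffles G across accessions, reconstructs Y* = P + G_shuffled, reruns
    the GLM scan with the same PC matrix and records the minimum p.  The
    threshold is -log10 of the alpha-quantile of those minima.
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype; permutation threshold undefined")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    P, G = structure_decomposition(y, pcs, n_pcs)
    rng = np.random.default_rng(seed)
    Ystar = np.empty((len(y), n_perm))
    for b in range(n_perm):
        Ystar[:, b] = P + rng.permutation(G)
    minima = min_p_scan_batch(panel, Ystar, pcs, n_pcs)
    q = float(np.quantile(minima, alpha))
    return PermutationThreshold(
        threshold=float(-np.log10(q)), minima=minima, n_perm=n_perm,
        alpha=alpha, seed=seed, n_pcs=n_pcs,
    )
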