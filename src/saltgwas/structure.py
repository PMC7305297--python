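"""Population structure: PCA, VanRaden kinship, neighbor-joining tree.

All three consume a QC-filtered :class:`~saltgwas.panel_io.GenotypePanel`.
Dosages are standardized per SNP as (d - 2p) / sqrt(2p(1-p)) with missing
entries set to 0 after centering (mean imputation); monomorphic SNPs
contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from saltgwas.panel_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PcResult:
    """Principal-component scores and variance shares.

    ``scores`` is (n_accessions, k); ``variance_explained`` the per-component
    share of total genotypic variance (non-increasing, each in [0,1]).
    """

    scores: np.ndarray
    variance_explained: np.ndarray
    loadings: np.ndarray | None = None


def standardized_dosages(panel: GenotypePanel) -> np.ndarray:
    """Center by 2p, scale by sqrt(2p(1-p)); missing and monomorphic -> 0."""
    d = panel.dosages_float()
    p = panel.allele_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[~np.isfinite(z)] = 0.0
    return z


def compute_pca(panel: GenotypePanel, k: int = 3) -> PcResult:
    """Top-k PCA of the standardized genotype matrix.

    Eigendecomposes the accession covariance ZZ'/m; variance explained is each
    eigenvalue's share of the trace.  ``k`` beyond the matrix rank is truncated
    with a warning.
    """
    z = standardized_dosages(panel)
    n, m = z.shape
    if m == 0:
        raise ValueError("empty panel")
    cov = z @ z.T / m
    vals, vecs = np.linalg.eigh(cov)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    vals = np.clip(vals, 0.0, None)
    rank = int(np.sum(vals > 1e-12 * max(vals[0], 1.0)))
    if k > rank:
        logger.warning("compute_pca: k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    total = vals.sum()
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    ve = vals[:k] / total if total > 0 else np.zeros(k)
    return PcResult(scores=scores, variance_explained=ve)


def compute_kinship(panel: GenotypePanel) -> np.ndarray:
    """VanRaden-style centered genomic relationship matrix K = ZZ'/m.

    Z is the standardized dosage matrix; m counts polymorphic SNPs only.
    """
    z = standardized_dosages(panel)
    p = panel.maf()
    poly = int(np.sum(np.nan_to_num(p) > 0))
    if poly == 0:
        raise ValueError("no polymorphic SNPs; kinship undefined")
    return z @ z.T / poly


def allele_sharing_distance(panel: GenotypePanel) -> np.ndarray:
    """1 - proportion of matching dosage calls over pairwise non-missing SNPs."""
    d = panel.dosages
    n = panel.n_accessions
    dist = np.zeros((n, n))
    valid = d != MISSING
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        match = (d[i] == d[i + 1:]) & both
        nb = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = 1.0 - match.sum(axis=1) / nb
        row[nb == 0] = 0.0
        dist[i, i + 1:] = dist[i + 1:, i] = row
    return dist


def neighbor_joining(panel: GenotypePanel, max_snps: int = 10_000) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) on allele-sharing distances.

    SNPs are thinned evenly by genome order to at most ``max_snps`` (every
    ceil(m/max_snps)-th SNP), mirroring an "evenly distributed" subset.
    Negative branch lengths are clamped to zero.
    """
    if panel.n_accessions < 3:
        raise ValueError("neighbor joining needs at least 3 accessions")
    m = panel.n_snps
    if m > max_snps:
        stride = int(np.ceil(m / max_snps))
        panel = panel.subset(snps=np.arange(0, m, stride))
    dist = allele_sharing_distance(panel)
    dm = DistanceMatrix(dist, ids=panel.accession_ids)
    tree = nj(dm)
    n_neg = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_neg += 1
    if n_neg:
        logger.info("neighbor_joining: clamped %d negative branch lengths to 0", n_neg)
    return tree


def deepest_bipartition(tree: TreeNode) -> tuple[set[str], set[str]]:
    """Leaf sets on either side of the longest internal edge.

    A convenience for checking that the deepest split of a two-subpopulation
    panel coincides with the subpopulation labels.
    """
    leaves = {t.name for t in tree.tips()}
    best, best_len = None, -1.0
    for node in tree.non_tips(include_self=False):
        if node.length is not None and node.length > best_len:
            best_len = node.length
            best = node
    if best is None:
        return leaves, set()
    side = {t.name for t in best.tips()}
    return side, leaves - side
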