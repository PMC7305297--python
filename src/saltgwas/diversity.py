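"""Nucleotide diversity, Tajima's D, and selection-signature classification.

Accessions are treated as haploid sequences (rice diversity panels are
essentially inbred): a homozygous-ref call contributes the reference allele, a
homozygous-alt call the alternate allele, and heterozygous or missing calls
are excluded per site.

π is the unbiased per-site heterozygosity sum, Σ_sites 2·p̂·q̂·n_s/(n_s−1) / L,
which for haploid-coded sequences equals the average pairwise difference count
divided by L; n_s adjusts per site for missingness.  Tajima's D is the
standard 1989 statistic, D = (π_total − S/a1) / sqrt(e1·S + e2·S·(S−1)), with
constants a1, a2, b1, b2, c1, c2, e1, e2 computed from the sequence count n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from saltgwas.panel_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    """Per-region, per-population diversity summary."""

    region_id: str
    population: str
    n: int  # sequences (accessions)
    L: int  # sites considered
    S: int  # segregating sites
    pi_per_site: float
    theta_w_per_site: float
    tajima_d: float | None  # None when S = 0


def _haploid_alleles(panel: GenotypePanel, snp_idx: np.ndarray) -> np.ndarray:
    """Accessions x sites haploid allele matrix: 0 (ref), 1 (alt), NaN (het/missing)."""
    d = panel.dosages[:, snp_idx].astype(float)
    out = np.full(d.shape, np.nan)
    out[d == 0] = 0.0
    out[d == 2] = 1.0
    return out


def _site_freqs(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt frequency, usable sequence count) over non-missing calls."""
    ns = np.sum(~np.isnan(h), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(h, axis=0) / ns
    return p, ns


def nucleotide_diversity(
    panel: GenotypePanel, snp_idx, L: int | None = None
) -> float:
    """π per site over the given SNP columns.

    ``L`` is the alignment length; by default, the number of sites with at
    least two usable sequences (monomorphic SNP records count toward L, so a
    toy with 100 sites and one difference between two sequences gives 0.01).
    """
    snp_idx = np.asarray(list(snp_idx))
    if snp_idx.size == 0:
        raise ValueError("empty region: L = 0")
    h = _haploid_alleles(panel, snp_idx)
    p, ns = _site_freqs(h)
    usable = ns >= 2
    if L is None:
        L = int(usable.sum())
    if L == 0:
        raise ValueError("no usable sites: L = 0")
    with np.errstate(invalid="ignore"):
        per_site = 2.0 * p * (1.0 - p) * ns / (ns - 1.0)
    return float(np.nansum(per_site[usable]) / L)


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(
    panel: GenotypePanel,
    snp_idx,
    population: str = "full",
    region_id: str = "region",
    L: int | None = None,
) -> DiversityStats:
    """Tajima's D (and π, θ_W, S) for a region.

    Constants use n = the number of accessions in the panel; per-site sequence
    counts only adjust the π estimator (exact when there are no missing or
    heterozygous calls).  D is reported as None when S = 0.  Requires n >= 4.
    """
    snp_idx = np.asarray(list(snp_idx))
    n = panel.n_accessions
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 sequences")
    h = _haploid_alleles(panel, snp_idx)
    p, ns = _site_freqs(h)
    usable = ns >= 2
    seg = usable & (p > 0) & (p < 1)
    S = int(seg.sum())
    if L is None:
        L = int(usable.sum())
    if L == 0:
        raise ValueError("no usable sites: L = 0")
    pi_site = nucleotide_diversity(panel, snp_idx, L=L)
    c = _tajima_constants(n)
    theta_w_total = S / c["a1"]
    if S == 0:
        return DiversityStats(region_id, population, n, L, 0, pi_site,
                              theta_w_total / L, None)
    pi_total = pi_site * L
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    d = (pi_total - theta_w_total) / np.sqrt(var)
    return DiversityStats(
        region_id=region_id, population=population, n=n, L=L, S=S,
        pi_per_site=pi_site, theta_w_per_site=theta_w_total / L,
        tajima_d=float(d),
    )


@dataclass
class SelectionCall:
    """Selection classification from a π ratio and Tajima's D."""

    region_id: str
    comparison: str
    pi_ratio: float | None  # reference π / focal π
    tajima_d: float | None
    call: str  # "positive selection" | "balancing selection" | "none"
    note: str = ""


def classify_selection(
    focal: DiversityStats,
    reference: DiversityStats,
    ratio_min: float = 2.0,
    d_significance_bounds: tuple[float, float] = (-1.8, 2.0),
) -> SelectionCall:
    """Classify selection in the focal population against a reference.

    Rules: π_ref/π_focal > ``ratio_min`` with focal D < 0 → "positive
    selection" (diversity loss plus rare-variant excess); π_focal/π_ref >
    ``ratio_min`` with focal D above the upper significance bound (large and
    positive) → "balancing selection"; otherwise "none".  The bounds default
    to Tajima's conventional ~5% beta-distribution confidence limits for
    moderate n and are exposed for other sample sizes; whether D falls outside
    them is recorded in the note either way.
    """
    region = focal.region_id
    comparison = f"{reference.population} vs {focal.population}"
    d = focal.tajima_d
    lo, hi = d_significance_bounds
    d_sig = d is not None and (d < lo or d > hi)
    note = f"D {'outside' if d_sig else 'within'} [{lo}, {hi}]"
    if reference.pi_per_site == 0 and focal.pi_per_site == 0:
        return SelectionCall(region, comparison, None, d, "none", "both π zero")
    if focal.pi_per_site == 0:
        return SelectionCall(region, comparison, None, d, "none",
                             "focal π zero; ratio undefined")
    ratio = reference.pi_per_site / focal.pi_per_site
    if ratio > ratio_min and d is not None and d < 0:
        return SelectionCall(region, comparison, ratio, d, "positive selection", note)
    if reference.pi_per_site > 0:
        inv = focal.pi_per_site / reference.pi_per_site
        if inv > ratio_min and d is not None and d > hi:
            return SelectionCall(region, comparison, ratio, d, "balancing selection", note)
    return SelectionCall(region, comparison, ratio, d, "none", note)
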