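"""Calibration and power experiments on synthetic panels.

These are the package's standing validation experiments: each one generates
panels under stated study conditions, runs the relevant scan machinery, and
returns the measured operating characteristic (type-I uniformity, structure
correction, permutation-threshold calibration, detection power, pyramiding
slope sign).  Both the test suite and the acceptance script drive them.

Problem sizes are desk-scale: 2,000 SNPs and a few hundred accessions per
replicate, which is where the statistical properties under test stabilize
without coalescent-scale data.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from saltgwas.assoc import ModelSpec, genomic_inflation, glm_scan, mlm_scan
from saltgwas.calibrate import (
    conditional_permutation_threshold,
    min_p_scan_batch,
    structure_decomposition,
)
from saltgwas.hapstats import pyramiding
from saltgwas.qtl import clump_signals
from saltgwas.structure import compute_kinship, compute_pca
from saltgwas.syndata import SimConfig, simulate_panel

# a prime stride decorrelates replicate seeds derived from one base seed
_STRIDE = 10_007


def _seed(base: int, i: int) -> int:
    return (base + i * _STRIDE) % (2**31 - 1)


def null_panel_config(seed: int, n_accessions: int = 300, n_snps: int = 2000) -> SimConfig:
    """A panmictic null panel: no divergence, no causal SNPs, no LD blocks
    (so SNP tests are mutually independent and uniformity is testable)."""
    return SimConfig(
        n_accessions=n_accessions, subpop_fractions=(1.0, 0.0), n_chrom=4,
        snps_per_chrom=n_snps // 4, fst=0.0, ld_block_mean_bp=0,
        n_founders=200, missing_rate=0.03, causal_snps=(), subpop_effect=0.0,
        seed=seed,
    )


def glm_type_i_uniformity(n_seeds: int = 50, base_seed: int = 0,
                          n_accessions: int = 300, n_snps: int = 2000) -> list[float]:
    """KS p-value of the GLM p distribution against uniform, per null replicate."""
    out = []
    for i in range(n_seeds):
        sim = simulate_panel(null_panel_config(_seed(base_seed, i), n_accessions, n_snps))
        y = sim.phenotypes["STL"].to_numpy(dtype=float)
        res = glm_scan(sim.genotypes, y, None, ModelSpec(model="GLM", n_pcs=0))
        p = res["p"].dropna().to_numpy()
        out.append(float(stats.kstest(p, "uniform").pvalue))
    return out


def structured_panel_config(seed: int, n_accessions: int = 300, n_snps: int = 2000) -> SimConfig:
    """Two diverged subpopulations (fst 0.3) with a phenotype offset and no
    causal SNPs: the structure-confounding scenario."""
    return SimConfig(
        n_accessions=n_accessions, subpop_fractions=(0.5, 0.5), n_chrom=4,
        snps_per_chrom=n_snps // 4, fst=0.3, missing_rate=0.03,
        causal_snps=(), subpop_effect=1.0, seed=seed,
    )


def structure_correction_lambdas(n_seeds: int = 50, base_seed: int = 0,
                                 n_accessions: int = 300, n_snps: int = 2000):
    """(lambda_GLM, lambda_MLM) per replicate under structure confounding.

    Both models run without PC covariates so the comparison isolates what the
    kinship random effect absorbs; the GLM is then fully exposed to the
    subpopulation mean shift while the MLM's leading kinship eigenvector
    captures it.
    """
    pairs = []
    for i in range(n_seeds):
        sim = simulate_panel(structured_panel_config(_seed(base_seed, i), n_accessions, n_snps))
        panel = sim.genotypes
        y = sim.phenotypes["STL"].to_numpy(dtype=float)
        K = compute_kinship(panel)
        g = glm_scan(panel, y, None, ModelSpec(model="GLM", n_pcs=0))
        m = mlm_scan(panel, y, None, K, ModelSpec(model="MLM", n_pcs=0))
        pairs.append((genomic_inflation(g), genomic_inflation(m)))
    return pairs


def permutation_calibration(base_seed: int = 0, n_perm: int = 200,
                            n_accessions: int = 300, n_snps: int = 2000,
                            alpha: float = 0.05, n_null: int = 200) -> dict:
    """Conditional vs naive permutation thresholds, plus achieved size.

    On an unstructured null panel the structure-conditional permutation must
    agree with plainly permuting Y (the PC fit explains ~nothing), and the
    fraction of fresh null scans whose minimum p beats the threshold must be
    close to alpha.  Fresh nulls redraw the phenotype noise on the same panel.
    """
    sim = simulate_panel(null_panel_config(_seed(base_seed, 0), n_accessions, n_snps))
    panel = sim.genotypes
    y = sim.phenotypes["STL"].to_numpy(dtype=float)
    pcs = compute_pca(panel, k=3)

    cond = conditional_permutation_threshold(
        panel, y, pcs, n_perm=n_perm, alpha=alpha, seed=_seed(base_seed, 1), n_pcs=3
    )
    rng = np.random.default_rng(_seed(base_seed, 2))
    Ynaive = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    naive_minima = min_p_scan_batch(panel, Ynaive, pcs, n_pcs=3)
    naive_thr = float(-np.log10(np.quantile(naive_minima, alpha)))

    rng2 = np.random.default_rng(_seed(base_seed, 3))
    Yfresh = rng2.normal(size=(n_accessions, n_null))
    fresh_minima = min_p_scan_batch(panel, Yfresh, pcs, n_pcs=3)
    frac = float(np.mean(-np.log10(fresh_minima) >= cond.threshold))
    return dict(
        conditional_threshold=cond.threshold,
        naive_threshold=naive_thr,
        naive_minima=naive_minima,
        fraction_exceeding=frac,
        alpha=alpha,
        n_perm=n_perm,
        n_null=n_null,
    )


def causal_recovery_config(seed: int, n_accessions: int = 500, n_snps: int = 2000) -> SimConfig:
    """One planted causal SNP in a structured panel; the effect size is set per
    replicate from the realized allele frequency (see causal_recovery_rate)."""
    per_chrom = n_snps // 4
    return SimConfig(
        n_accessions=n_accessions, subpop_fractions=(0.65, 0.35), n_chrom=4,
        snps_per_chrom=per_chrom, fst=0.3, missing_rate=0.03,
        causal_snps=((1, per_chrom // 2, 1.0),), subpop_effect=0.3, seed=seed,
    )


def causal_recovery_rate(n_seeds: int = 100, base_seed: int = 0,
                         threshold: float = 4.0, h2: float = 0.3) -> float:
    """Fraction of replicates where the planted SNP is the lead of a detected signal.

    The liability effect is rescaled per replicate so the planted SNP explains
    ``h2`` of the liability variance at its realized frequency,
    b = sqrt(h2/(1-h2)) / sqrt(2pq); under Balding-Nichols divergence the
    realized frequency can drift far from its ancestral draw, and the
    experiment's premise is the per-replicate heritability, not the ancestral
    one.  A replicate whose planted SNP comes out monomorphic has no causal
    variant to recover (h2 = 0, the condition is not instantiated), so it is
    redrawn with a derived seed.
    """
    from saltgwas.syndata import simulate_phenotype

    hits = 0
    draw = 0
    for i in range(n_seeds):
        while True:
            cfg = causal_recovery_config(_seed(base_seed, i + n_seeds * (1 + draw)))
            sim = simulate_panel(cfg)
            panel = sim.genotypes
            j = sim.causal_indices()[0]
            p_alt = float(panel.allele_freq()[j])
            var = 2.0 * p_alt * (1.0 - p_alt)
            if var > 0:
                break
            draw += 1
        sim.truth["causal_effects"] = [float(np.sqrt(h2 / (1.0 - h2) / var))]
        sim.phenotypes = simulate_phenotype(sim, cfg)
        pcs = compute_pca(panel, k=3)
        y = sim.phenotypes["STL"].to_numpy(dtype=float)
        res = glm_scan(panel, y, pcs, ModelSpec(model="GLM", n_pcs=3))
        signals = clump_signals(res, threshold)
        leads = {s.lead_id for s in signals}
        hits += bool(leads & set(sim.truth["causal_ids"]))
    return hits / n_seeds


def pyramiding_slopes(n_seeds: int = 40, base_seed: int = 0,
                      threshold: float = 4.0) -> list[float]:
    """Pyramiding regression slope per replicate with 5 additive causal SNPs.

    Slopes should be negative: more superior alleles, lower STL.
    Replicates yielding fewer than two detected signals are recorded as NaN.
    """
    slopes = []
    for i in range(n_seeds):
        per_chrom = 500
        causal = tuple((c, per_chrom // 4 + 37 * c, 0.75) for c in range(4)) + ((0, 400, 0.75),)
        cfg = SimConfig(
            n_accessions=400, subpop_fractions=(0.6, 0.4), n_chrom=4,
            snps_per_chrom=per_chrom, fst=0.3, missing_rate=0.03,
            causal_snps=causal, subpop_effect=0.3, noise_sd=1.0,
            seed=_seed(base_seed, i),
        )
        sim = simulate_panel(cfg)
        panel = sim.genotypes
        pcs = compute_pca(panel, k=3)
        y = sim.phenotypes["STL"].to_numpy(dtype=float)
        res = glm_scan(panel, y, pcs, ModelSpec(model="GLM", n_pcs=3))
        signals = clump_signals(res, threshold)
        if len(signals) < 2:
            slopes.append(float("nan"))
            continue
        pyr = pyramiding(panel, signals, sim.phenotypes)
        slopes.append(pyr.slope)
    return slopes
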