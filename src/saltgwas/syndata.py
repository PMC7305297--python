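"""Synthetic genotype-phenotype panels with rice-diversity-panel structure.

The generator emulates the statistical features the downstream analyses rely on:

* two diverged subpopulations (an *indica*/*japonica*-like split) whose allele
  frequencies follow a Balding-Nichols divergence model at a configurable Fst;
* blockwise linkage disequilibrium produced by copying founder haplotypes in
  contiguous blocks of exponentially distributed length (mean ~170 kb by
  default, the decay scale reported for rice diversity panels);
* a MAF spectrum with rare variants, plus random missing calls;
* a handful of planted causal SNPs feeding an additive liability, a
  subpopulation offset, and Gaussian noise; the liability is discretized into
  the ordinal 1-9 salt-tolerance level (STL, lower = more tolerant) and six
  auxiliary continuous seedling traits are generated as correlated noise.

Everything is deterministic given the single seed in :class:`SimConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from saltgwas.panel_io import (
    MISSING,
    SNP_COLUMNS,
    GenotypePanel,
    write_phenotypes,
    write_vcf,
)

SUBPOP_LABELS = ("indica", "japonica")

# Auxiliary continuous traits: (mean, SD) on the scale of a hydroponic
# seedling salt assay (shoot/root lengths in mm, fresh/dry weights in g).
_AUX_TRAITS = {
    "SL": (23.1, 3.8),
    "SFW": (0.48, 0.14),
    "SDW": (0.15, 0.04),
    "RL": (15.4, 2.9),
    "RFW": (0.49, 0.15),
    "RDW": (0.06, 0.02),
}


@dataclass
class SimConfig:
    """Configuration of a simulated diversity panel.

    Defaults mirror the study conditions of a 664-accession cultivated-rice
    panel with a 428/236 indica/japonica split, 12 chromosomes, ~170 kb LD
    blocks and a modest missing-call rate; SNP density is desk-scale.
    """

    n_accessions: int = 664
    subpop_fractions: tuple[float, float] = (428 / 664, 236 / 664)
    n_chrom: int = 12
    snps_per_chrom: int = 250
    chrom_length_bp: int = 25_000_000
    ld_block_mean_bp: int = 170_000
    fst: float = 0.3
    maf_min: float = 0.05
    missing_rate: float = 0.03
    #: planted causal SNPs: (chrom index 0-based, snp index within chrom, liability effect)
    causal_snps: tuple[tuple[int, int, float], ...] = ()
    subpop_effect: float = 0.0
    noise_sd: float = 1.0
    n_founders: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.subpop_fractions
        if len(f) != 2 or abs(sum(f) - 1.0) > 1e-8 or any(x < 0 or x > 1 for x in f):
            raise ValueError("subpop_fractions must be two proportions summing to 1")
        for name in ("maf_min", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0,1)")
        for c, j, _ in self.causal_snps:
            if not (0 <= c < self.n_chrom and 0 <= j < self.snps_per_chrom):
                raise ValueError(f"causal SNP (chrom {c}, index {j}) out of bounds")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subpop_fractions" in raw:
            raw["subpop_fractions"] = tuple(raw["subpop_fractions"])
        if "causal_snps" in raw:
            raw["causal_snps"] = tuple(tuple(x) for x in raw["causal_snps"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["subpop_fractions"] = list(self.subpop_fractions)
        d["causal_snps"] = [list(x) for x in self.causal_snps]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class SimulatedPanel:
    """A generated panel plus its phenotypes and ground truth."""

    genotypes: GenotypePanel
    phenotypes: pd.DataFrame
    truth: dict

    def causal_indices(self) -> list[int]:
        """Genome-wide column indices of the planted causal SNPs."""
        ids = set(self.truth["causal_ids"])
        snps = self.genotypes.snps
        return [j for j in range(len(snps)) if snps["id"].iat[j] in ids]


def _draw_subpop_freqs(rng: np.random.Generator, p_anc: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies given ancestral p and Fst."""
    if fst == 0.0:
        return np.stack([p_anc, p_anc])
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.stack([rng.beta(a, b), rng.beta(a, b)])


def _haplotypes_from_founders(
    rng: np.random.Generator,
    founders: np.ndarray,
    pos: np.ndarray,
    n_hap: int,
    mean_block_bp: float,
) -> np.ndarray:
    """Build haplotypes by copying founder rows in exponential-length blocks.

    ``founders`` is (n_founders, n_snps) of 0/1 alleles; returns (n_hap, n_snps).
    ``mean_block_bp <= 0`` picks an independent founder per SNP (no LD beyond
    the founder-pool sharing at distance zero).
    """
    n_founders, m = founders.shape
    if mean_block_bp <= 0:
        choice = rng.integers(0, n_founders, size=(n_hap, m))
        return founders[choice, np.arange(m)]
    out = np.empty((n_hap, m), dtype=np.int8)
    span = (pos[-1] - pos[0]) if m > 1 else 1
    # expected block count per haplotype, with head room; extended if short
    k_guess = max(int(span / mean_block_bp * 1.6) + 8, 4)
    cols = np.arange(m)
    for h in range(n_hap):
        lengths = rng.exponential(mean_block_bp, size=k_guess)
        while lengths.sum() < span:
            lengths = np.concatenate([lengths, rng.exponential(mean_block_bp, size=k_guess)])
        bounds = pos[0] + np.cumsum(lengths)
        block_of = np.searchsorted(bounds, pos, side="right")
        founder_of_block = rng.integers(0, n_founders, size=block_of.max() + 1)
        out[h] = founders[founder_of_block[block_of], cols]
    return out


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Generate a full panel (genotypes + phenotypes + truth) from ``config``.

    Per chromosome: ancestral allele frequencies are drawn uniform on
    [maf_min, 1-maf_min], diverged into two subpopulation frequencies by the
    Balding-Nichols model, founder haplotypes are sampled per subpopulation,
    and each accession receives two independent haplotypes assembled by
    founder-block copying (so genotypes are in Hardy-Weinberg proportions
    within subpopulations).  Missing calls are inserted uniformly at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_accessions
    n1 = int(round(n * config.subpop_fractions[0]))
    subpop = np.array([0] * n1 + [1] * (n - n1))
    acc_ids = [f"ACC{i + 1:04d}" for i in range(n)]

    snp_frames = []
    dosage_cols = []
    causal_by_chrom: dict[int, list[tuple[int, float]]] = {}
    for c, j, eff in config.causal_snps:
        causal_by_chrom.setdefault(c, []).append((j, eff))

    for c in range(config.n_chrom):
        m = config.snps_per_chrom
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False)
        )
        p_anc = rng.uniform(config.maf_min, 1.0 - config.maf_min, size=m)
        p_sub = _draw_subpop_freqs(rng, p_anc, config.fst)

        chrom_dos = np.empty((n, m), dtype=np.int8)
        for k, n_k in ((0, n1), (1, n - n1)):
            if n_k == 0:
                continue
            founders = (
                rng.random((config.n_founders, m)) < p_sub[k]
            ).astype(np.int8)
            h1 = _haplotypes_from_founders(rng, founders, pos, n_k, config.ld_block_mean_bp)
            h2 = _haplotypes_from_founders(rng, founders, pos, n_k, config.ld_block_mean_bp)
            chrom_dos[subpop == k] = h1 + h2

        chrom = f"chr{c + 1:02d}"
        ids = [f"{chrom}_{p}" for p in pos]
        snp_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "id": ids, "ref": "A", "alt": "G"},
                columns=SNP_COLUMNS,
            )
        )
        dosage_cols.append(chrom_dos)

    dosages = np.concatenate(dosage_cols, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    snps = pd.concat(snp_frames, ignore_index=True)
    panel = GenotypePanel(accession_ids=acc_ids, snps=snps, dosages=dosages)

    causal_ids = []
    causal_effects = []
    for c, j, eff in config.causal_snps:
        gidx = c * config.snps_per_chrom + j
        causal_ids.append(snps["id"].iat[gidx])
        causal_effects.append(eff)
    truth = {
        "causal_ids": causal_ids,
        "causal_effects": causal_effects,
        "subpop": [SUBPOP_LABELS[s] for s in subpop],
        "seed": config.seed,
    }
    sim = SimulatedPanel(genotypes=panel, phenotypes=pd.DataFrame(), truth=truth)
    sim.phenotypes = simulate_phenotype(sim, config)
    return sim


def simulate_phenotype(panel: SimulatedPanel, config: SimConfig) -> pd.DataFrame:
    """Generate the phenotype table from the genotypes and config.

    liability = sum(effect * dosage) + subpop_effect * 1{subpop2} + N(0, noise_sd).
    A missing genotype at a causal SNP contributes twice the alt-allele frequency
    (its expectation).  STL is the liability cut into 9 equal-width bins over its
    observed range, reported on the 1-9 scale; the six auxiliary traits are
    correlated Gaussian noise sharing a latent vigor factor with the liability.
    """
    geno = panel.genotypes
    # phenotype stream independent of the genotype stream but tied to the seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = geno.n_accessions
    subpop = np.array([0 if s == SUBPOP_LABELS[0] else 1 for s in panel.truth["subpop"]])

    liab = np.zeros(n)
    ids = list(geno.snps["id"])
    for snp_id, eff in zip(panel.truth["causal_ids"], panel.truth["causal_effects"]):
        j = ids.index(snp_id)
        d = geno.dosages[:, j].astype(float)
        freq = np.mean(d[d != MISSING]) / 2.0 if np.any(d != MISSING) else 0.0
        d[geno.dosages[:, j] == MISSING] = 2.0 * freq
        liab += eff * d
    liab += config.subpop_effect * subpop
    noise = rng.normal(0.0, config.noise_sd, size=n)
    liab += noise

    lo, hi = liab.min(), liab.max()
    if hi > lo:
        stl = 1 + np.floor(9 * (liab - lo) / (hi - lo)).astype(int)
        stl = np.clip(stl, 1, 9)
    else:
        stl = np.full(n, 5, dtype=int)

    # shared latent "vigor" couples the auxiliary traits to each other and,
    # weakly and negatively, to salt damage
    vigor = -0.4 * (liab - liab.mean()) / (liab.std() or 1.0) + rng.normal(0, 1, n)
    pheno = pd.DataFrame({"accession_id": geno.accession_ids,
                          "subpop": [SUBPOP_LABELS[s] for s in subpop]})
    for trait, (mu, sd) in _AUX_TRAITS.items():
        z = 0.6 * vigor + 0.8 * rng.normal(0, 1, n)
        pheno[trait] = np.clip(mu + sd * z, 0.01, None)
    pheno["STL"] = stl
    return pheno


def write_sim(sim: SimulatedPanel, vcf_path: str, pheno_path: str, truth_path: str) -> None:
    """Write a simulated panel as VCF + phenotype TSV + truth JSON."""
    write_vcf(sim.genotypes, vcf_path)
    write_phenotypes(sim.phenotypes, pheno_path)
    with open(truth_path, "w") as fh:
        json.dump(sim.truth, fh, indent=1)


def hudson_fst(panel: GenotypePanel, labels: np.ndarray) -> float:
    """Hudson's Fst between two labeled groups, averaged over SNPs (ratio of sums).

    ``labels`` is a 0/1 array per accession.  Used to verify that realized
    divergence tracks the configured Balding-Nichols Fst.
    """
    d = panel.dosages_float()
    d0, d1 = d[labels == 0], d[labels == 1]
    with np.errstate(invalid="ignore"):
        p0 = np.nanmean(d0, axis=0) / 2.0
        p1 = np.nanmean(d1, axis=0) / 2.0
        n0 = np.sum(~np.isnan(d0), axis=0) * 2
        n1 = np.sum(~np.isnan(d1), axis=0) * 2
    ok = (n0 > 1) & (n1 > 1) & ~np.isnan(p0) & ~np.isnan(p1)
    p0, p1, n0, n1 = p0[ok], p1[ok], n0[ok], n1[ok]
    num = (p0 - p1) ** 2 - p0 * (1 - p0) / (n0 - 1) - p1 * (1 - p1) / (n1 - 1)
    den = p0 * (1 - p1) + p1 * (1 - p0)
    return float(num.sum() / den.sum())
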