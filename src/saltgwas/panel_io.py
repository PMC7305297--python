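"""Genotype/phenotype containers, VCF and TSV I/O, SNP QC, descriptive statistics.

The central container is :class:`GenotypePanel`: an accessions x SNPs matrix of
alt-allele dosages (0/1/2, ``MISSING`` = -1 for no-calls) plus ordered SNP records
and accession identifiers.  Dosage coding follows the VCF GT field: ``0/1`` -> 1,
``1/1`` -> 2, ``./.`` -> missing.  Positions are 1-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

TRAITS = ["SL", "SFW", "SDW", "RL", "RFW", "RDW", "STL"]

SNP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypePanel:
    """Accessions x biallelic SNPs with dosage coding and missingness.

    Attributes
    ----------
    accession_ids : list of str
        Row labels of the dosage matrix.
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``; positions
        strictly increasing within each chromosome.
    dosages : numpy.ndarray of int8, shape (n_accessions, n_snps)
        Alt-allele counts in {0, 1, 2}, ``MISSING`` (-1) for no-calls.
    """

    accession_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.accession_ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.snps)} SNPs"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def dosages_float(self) -> np.ndarray:
        """Dosage matrix as float with NaN for missing calls."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if all missing)."""
        d = self.dosages_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per SNP."""
        return (self.dosages == MISSING).mean(axis=0)

    def subset(self, accessions=None, snps=None) -> "GenotypePanel":
        """Return a new panel restricted to the given accession / SNP indices."""
        acc_idx = np.arange(self.n_accessions) if accessions is None else np.asarray(accessions)
        snp_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypePanel(
            accession_ids=[self.accession_ids[i] for i in acc_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            dosages=self.dosages[np.ix_(acc_idx, snp_idx)].copy(),
        )

    def snp_indices_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of SNPs on ``chrom`` with ``start <= pos <= end`` (1-based inclusive)."""
        m = (self.snps["chrom"] == chrom) & (self.snps["pos"] >= start) & (self.snps["pos"] <= end)
        return np.flatnonzero(m.to_numpy())


# ---------------------------------------------------------------------------
# VCF / phenotype I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypePanel:
    """Read a diploid biallelic VCF into a :class:`GenotypePanel`.

    Multiallelic sites are skipped (a count is logged).  Any genotype with a
    no-call allele becomes ``MISSING``.
    """
    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    records = []
    columns = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = v.genotypes  # [[a1, a2, phased], ...]
        col = np.empty(len(accession_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            a1, a2 = g[0], g[1]
            col[i] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
        records.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0]))
        columns.append(col)
    if n_multi:
        logger.info("read_vcf: skipped %d multiallelic sites", n_multi)
    snps = pd.DataFrame(records, columns=SNP_COLUMNS)
    dosages = (
        np.stack(columns, axis=1) if columns else np.empty((len(accession_ids), 0), dtype=np.int8)
    )
    return GenotypePanel(accession_ids=accession_ids, snps=snps, dosages=dosages)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as a minimal VCF 4.2 file with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=saltgwas\n##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.accession_ids) + "\n")
        snps = panel.snps
        for j in range(panel.n_snps):
            row = snps.iloc[j]
            gts = "\t".join(_GT[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read the tab-separated phenotype file.

    Expected columns: ``accession_id``, ``subpop`` and the seven traits
    (SL, SFW, SDW, RL, RFW, RDW, STL).  STL must lie in [1, 9] where present.
    """
    df = pd.read_csv(path, sep="\t")
    if "accession_id" not in df.columns:
        raise ValueError("phenotype file lacks an accession_id column")
    if df["accession_id"].duplicated().any():
        raise ValueError("duplicate accession_id in phenotype file")
    if "STL" in df.columns:
        stl = df["STL"].dropna()
        if ((stl < 1) | (stl > 9)).any():
            raise ValueError("STL values outside the 1-9 ordinal scale")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_panel(vcf_path: str, phenotype_path: str) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read genotype VCF and phenotype TSV, intersect accessions, align order.

    Raises ``ValueError`` if no accession appears in both files.
    """
    panel = read_vcf(vcf_path)
    pheno = read_phenotypes(phenotype_path)
    common = [a for a in panel.accession_ids if a in set(pheno["accession_id"])]
    if not common:
        raise ValueError("no overlapping accessions between VCF and phenotype file")
    dropped = panel.n_accessions - len(common) + (len(pheno) - len(common))
    if dropped:
        logger.info("read_panel: %d accessions present in only one file were dropped", dropped)
    idx = [panel.accession_ids.index(a) for a in common]
    panel = panel.subset(accessions=idx)
    pheno = pheno.set_index("accession_id").loc[common].reset_index()
    return panel, pheno


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_snps(
    panel: GenotypePanel, max_missing: float = 0.30, min_maf: float = 0.05
) -> GenotypePanel:
    """Apply the study's SNP QC: drop SNPs with missing rate > ``max_missing``
    or MAF < ``min_maf`` (computed over non-missing calls).

    The boundary is inclusive on the keep side: a SNP at exactly 30% missing or
    exactly 5% MAF survives.  Returns a (possibly empty) new panel.
    """
    miss = panel.missing_rate()
    maf = panel.maf()
    with np.errstate(invalid="ignore"):
        keep = (miss <= max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    n_miss = int(np.sum(miss > max_missing))
    n_maf = int(np.sum(~keep & (miss <= max_missing)))
    logger.info(
        "filter_snps: removed %d by missingness (> %.2f), %d by MAF (< %.2f); %d/%d retained",
        n_miss, max_missing, n_maf, min_maf, int(keep.sum()), panel.n_snps,
    )
    if not keep.any():
        logger.warning("filter_snps: all SNPs removed")
    return panel.subset(snps=np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def trait_summary(pheno: pd.DataFrame, by_subpop: bool = True) -> pd.DataFrame:
    """Per-trait descriptive statistics in the style of a diversity-panel table.

    For each trait (and subpopulation when ``by_subpop``): min, max, mean,
    sample SD (n-1), moment skewness, excess kurtosis, and CV = SD/mean as a
    fraction.  Skewness/kurtosis are reported as NaN for constant traits.
    Requires at least two non-missing values per group; groups below that are
    omitted.
    """
    rows = []
    groups = pheno.groupby("subpop") if (by_subpop and "subpop" in pheno.columns) else [("all", pheno)]
    for label, grp in groups:
        for trait in TRAITS:
            if trait not in grp.columns:
                continue
            x = grp[trait].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                continue
            mean = x.mean()
            sd = x.std(ddof=1)
            if sd == 0:
                skew = kurt = np.nan
            else:
                skew = stats.skew(x, bias=True)
                kurt = stats.kurtosis(x, fisher=True, bias=True)
            cv = sd / mean if mean > 0 else np.nan
            rows.append(
                dict(trait=trait, subpop=label, n=len(x), min=x.min(), max=x.max(),
                     mean=mean, sd=sd, skewness=skew, kurtosis=kurt, cv=cv)
            )
    return pd.DataFrame(rows)


def trait_correlations(pheno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations among the seven traits.

    Returns (r, p) DataFrames.  Entries with fewer than 3 complete pairs are NaN;
    the diagonal is exactly 1 with p = 0.
    """
    traits = [t for t in TRAITS if t in pheno.columns]
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = pheno[[traits[i], traits[j]]].dropna()
            if len(sub) < 3:
                continue
            res = stats.pearsonr(sub[traits[i]], sub[traits[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )
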