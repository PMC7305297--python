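"""Haplotype construction, group phenotype tests with Duncan letters,
combination haplotypes, and superior-allele pyramiding.

Haplotypes are built over a small set of candidate functional sites
(nonsynonymous SNPs above a −log10 p cutoff plus significant promoter SNPs).
Accessions heterozygous or missing at any site are left unassigned — rice
diversity panels are essentially inbred, so heterozygous calls are treated as
unreliable.  Group phenotype differences use Welch's t (2 groups) or one-way
ANOVA (≥3), followed by Duncan's multiple range test: critical ranges from the
studentized-range distribution at the Duncan protection level
alpha_p = 1 − (1 − alpha)^(p−1), with the harmonic-mean group size for
unbalanced designs.  "Superior" always means the lowest mean STL (STL is a
damage score; lower = more salt tolerant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from saltgwas.panel_io import MISSING, GenotypePanel
from saltgwas.qtl import CandidateRegion, QtlSignal

logger = logging.getLogger(__name__)

RARE = "rare"


@dataclass
class HaplotypeTable:
    """Per-accession haplotype assignment over a selected SNP set."""

    region_id: str
    sites: pd.DataFrame  # columns: id, pos, ref, alt, annotation, log10p
    assignments: pd.Series  # accession_id -> hap label (NaN = unassigned)
    groups: pd.DataFrame  # columns: hap, allele_string, n

    def assigned(self) -> pd.Series:
        """Assignments restricted to named (non-rare, non-missing) groups."""
        s = self.assignments.dropna()
        return s[s != RARE]


def build_haplotypes(
    panel: GenotypePanel,
    region: CandidateRegion,
    scan: pd.DataFrame,
    site_annotations: dict[str, str],
    min_logp: float = 2.0,
    promoter_logp: float = 4.0,
    min_group: int = 10,
    region_id: str | None = None,
) -> HaplotypeTable:
    """Build haplotypes over candidate functional sites in a region.

    The site set is: nonsynonymous SNPs with −log10 p > ``min_logp`` plus
    promoter SNPs with −log10 p >= ``promoter_logp`` (genome-wide significant),
    both restricted to the region members.  ``site_annotations`` maps SNP id to
    one of {"nonsynonymous", "promoter", "other"}.  Accessions with a missing
    or heterozygous call at any site are unassigned; identical allele strings
    are grouped; groups smaller than ``min_group`` are pooled as "rare".
    """
    logp = scan.set_index("id")["log10p"]
    site_ids = []
    for sid in region.members["id"]:
        ann = site_annotations.get(sid, "other")
        lp = float(logp.get(sid, np.nan))
        if ann == "nonsynonymous" and lp > min_logp:
            site_ids.append(sid)
        elif ann == "promoter" and lp >= promoter_logp:
            site_ids.append(sid)
    if not site_ids:
        raise ValueError("no qualifying sites (no annotated SNP passes the cutoffs)")

    snp_index = {panel.snps["id"].iat[j]: j for j in range(panel.n_snps)}
    cols = [snp_index[s] for s in site_ids]
    sites = panel.snps.iloc[cols][["id", "pos", "ref", "alt"]].copy()
    sites["annotation"] = [site_annotations.get(s, "other") for s in site_ids]
    sites["log10p"] = [float(logp.get(s, np.nan)) for s in site_ids]
    sites = sites.reset_index(drop=True)

    d = panel.dosages[:, cols]
    alleles = np.full(d.shape, "?", dtype="U1")
    for k in range(len(cols)):
        ref, alt = sites["ref"].iat[k], sites["alt"].iat[k]
        alleles[d[:, k] == 0, k] = ref
        alleles[d[:, k] == 2, k] = alt
    ok = ~np.any((d == 1) | (d == MISSING), axis=1)
    strings = np.array(["".join(row) for row in alleles])

    assign = pd.Series(np.nan, index=pd.Index(panel.accession_ids, name="accession_id"), dtype=object)
    counts = pd.Series(strings[ok]).value_counts()
    label_of = {}
    rank = 1
    for s, c in counts.items():
        if c >= min_group:
            label_of[s] = f"hap{rank}"
            rank += 1
        else:
            label_of[s] = RARE
    for i in np.flatnonzero(ok):
        assign.iloc[i] = label_of[strings[i]]
    groups = pd.DataFrame(
        [dict(hap=label_of[s], allele_string=s, n=int(c)) for s, c in counts.items()]
    )
    return HaplotypeTable(
        region_id=region_id or f"{region.chrom}:{region.start}-{region.end}",
        sites=sites, assignments=assign, groups=groups,
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_letters(
    means: np.ndarray, ns: np.ndarray, mse: float, df_err: int, alpha: float = 0.01
) -> list[str]:
    """Compact letter display from Duncan's multiple range test.

    Groups are sorted by mean; two groups spanning p consecutive ranks differ
    when their mean difference exceeds
    R_p = q(1-alpha_p; p, df_err) * sqrt(MSE / n_h), alpha_p = 1-(1-alpha)^(p-1),
    with n_h the harmonic mean group size.  Maximal runs of mutually
    non-different groups share a letter; letter 'a' starts at the smallest mean.
    Returns one (possibly multi-) letter string per group, in input order.
    """
    k = len(means)
    order = np.argsort(means, kind="stable")
    sm = means[order]
    n_h = k / np.sum(1.0 / ns)
    sem = np.sqrt(mse / n_h)

    def differ(i: int, j: int) -> bool:
        span = abs(i - j) + 1
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, span, df_err)
        return abs(sm[i] - sm[j]) > q * sem

    # maximal runs of consecutive sorted groups whose extremes do not differ
    # (the multiple-range protection: subranges of a non-significant range are
    # never declared different)
    candidates = []
    for i in range(k):
        j = k - 1
        while j > i and differ(i, j):
            j -= 1
        if (i, j) not in candidates:
            candidates.append((i, j))
    runs = [
        r for r in candidates
        if not any(o != r and o[0] <= r[0] and o[1] >= r[1] for o in candidates)
    ]
    letters_sorted = ["" for _ in range(k)]
    for li, (a, b) in enumerate(runs):
        ch = chr(ord("a") + li)
        for g in range(a, b + 1):
            letters_sorted[g] += ch
    out = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        out[orig] = letters_sorted[pos]
    return out


@dataclass
class HaplotypeTestResult:
    """Group phenotype comparison for one population."""

    population: str
    stats: pd.DataFrame  # hap, n, mean, sd, letter
    test: str  # "t" or "anova"
    statistic: float
    p: float
    alpha: float
    superior: str | None  # minimum-mean lettered group (None if no groups)


def _group_test(
    groups: dict[str, np.ndarray], alpha: float, population: str
) -> HaplotypeTestResult:
    names = sorted(groups, key=lambda h: (len(h), h))
    arrays = [groups[h] for h in names]
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    if len(names) == 2:
        test = "t"
        statistic, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
    else:
        test = "anova"
        statistic, p = stats.f_oneway(*arrays)
    n_tot = int(ns.sum())
    df_err = n_tot - len(names)
    mse = float(sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / df_err)
    if p < alpha:
        letters = duncan_letters(means, ns, mse, df_err, alpha=alpha)
    else:
        letters = ["a"] * len(names)
    table = pd.DataFrame(dict(hap=names, n=ns, mean=means, sd=sds, letter=letters))
    superior = names[int(np.argmin(means))] if names else None
    return HaplotypeTestResult(
        population=population, stats=table, test=test,
        statistic=float(statistic), p=float(p), alpha=alpha, superior=superior,
    )


def compare_haplotypes(
    table: HaplotypeTable,
    pheno: pd.DataFrame,
    trait: str = "STL",
    by_population: bool = True,
    alpha: float = 0.01,
    min_n: int = 2,
) -> dict[str, HaplotypeTestResult]:
    """Phenotype comparison between haplotype groups, per population.

    Two groups → Welch's t; three or more → one-way ANOVA; Duncan letters are
    assigned when the omnibus test is significant at ``alpha``.  Groups with
    fewer than ``min_n`` phenotyped accessions in a population are excluded
    with a warning.  Returns a mapping population → result.
    """
    ph = pheno.set_index("accession_id")
    assign = table.assigned()
    pops = sorted(ph.loc[assign.index, "subpop"].unique()) if by_population else ["all"]
    out: dict[str, HaplotypeTestResult] = {}
    for pop in pops:
        if by_population:
            acc = [a for a in assign.index if ph.at[a, "subpop"] == pop]
        else:
            acc = list(assign.index)
        groups: dict[str, np.ndarray] = {}
        for hap in assign.loc[acc].unique():
            members = [a for a in acc if assign[a] == hap]
            vals = ph.loc[members, trait].dropna().to_numpy(dtype=float)
            if len(vals) >= min_n:
                groups[hap] = vals
            else:
                logger.warning("compare_haplotypes: %s/%s has n=%d < %d; excluded",
                               pop, hap, len(vals), min_n)
        if len(groups) < 2:
            continue
        out[pop] = _group_test(groups, alpha, pop)
    return out


@dataclass
class ComboResult:
    """Cross-classification of two genes' haplotypes."""

    combos: pd.DataFrame  # co_hap, hap1, hap2, n, mean, sd, letter, class
    test: HaplotypeTestResult
    assignments: pd.Series  # accession -> co-hap label


def combine_haplotypes(
    table1: HaplotypeTable,
    table2: HaplotypeTable,
    pheno: pd.DataFrame,
    trait: str = "STL",
    alpha: float = 0.05,
) -> ComboResult:
    """Combination-haplotype analysis of two genes.

    Accessions assigned at both genes are cross-classified; combinations are
    labeled co-hap1..co-hapK in (hap1, hap2) lexical order over the cross
    product.  One-way ANOVA with Duncan letters at ``alpha``; a combination is
    classed "superior" if it carries the best (lowest-mean) letter only,
    "inferior" if the worst letter only, else "intermediate".
    """
    a1, a2 = table1.assigned(), table2.assigned()
    common = a1.index.intersection(a2.index)
    pairs = pd.DataFrame({"h1": a1.loc[common], "h2": a2.loc[common]})
    haps1 = sorted(a1.unique())
    haps2 = sorted(a2.unique())
    labels = {}
    k = 1
    for h1, h2 in product(haps1, haps2):
        sub = pairs[(pairs["h1"] == h1) & (pairs["h2"] == h2)]
        if len(sub):
            labels[(h1, h2)] = f"co-hap{k}"
            k += 1
    if len(labels) < 2:
        raise ValueError("fewer than 2 populated haplotype combinations")
    assign = pd.Series(
        [labels[(r.h1, r.h2)] for r in pairs.itertuples()], index=common, dtype=object
    )
    ph = pheno.set_index("accession_id")
    groups = {
        lab: ph.loc[assign[assign == lab].index, trait].dropna().to_numpy(dtype=float)
        for lab in labels.values()
    }
    groups = {k_: v for k_, v in groups.items() if len(v) >= 2}
    test = _group_test(groups, alpha, "all")

    st = test.stats.set_index("hap")
    distinct = sorted(set("".join(st["letter"])))
    rows = []
    for (h1, h2), lab in labels.items():
        if lab not in st.index:
            continue
        letters = set(st.at[lab, "letter"])
        if len(distinct) == 1:
            cls = "intermediate"
        elif distinct[0] in letters and distinct[-1] not in letters:
            cls = "superior"
        elif distinct[-1] in letters and distinct[0] not in letters:
            cls = "inferior"
        else:
            cls = "intermediate"
        rows.append(dict(co_hap=lab, hap1=h1, hap2=h2, n=int(st.at[lab, "n"]),
                         mean=st.at[lab, "mean"], sd=st.at[lab, "sd"],
                         letter=st.at[lab, "letter"], **{"class": cls}))
    combos = pd.DataFrame(rows)
    return ComboResult(combos=combos, test=test, assignments=assign)


@dataclass
class PyramidResult:
    """Superior-allele counts and the count → mean-STL regression."""

    counts: pd.Series  # accession -> number of homozygous-superior lead SNPs
    group_means: pd.DataFrame  # count, n, mean
    slope: float
    intercept: float
    r2: float


def pyramiding(
    panel: GenotypePanel,
    signals: list[QtlSignal],
    pheno: pd.DataFrame,
    trait: str = "STL",
    per_accession: bool = False,
) -> PyramidResult:
    """Count superior alleles over the lead-SNP set and regress STL on the count.

    For each lead SNP the superior allele is the homozygous genotype class
    (dosage 0 or 2) with the lower mean STL; leads with a single genotype
    class are dropped with a warning.  Each accession's count is its number of
    homozygous-superior leads.  By default the regression is of per-count group
    mean STL on count; ``per_accession`` regresses individual values instead.
    """
    ph = pheno.set_index("accession_id")
    y = ph.loc[panel.accession_ids, trait].to_numpy(dtype=float)
    snp_index = {panel.snps["id"].iat[j]: j for j in range(panel.n_snps)}
    superior_dosage: dict[str, int] = {}
    for s in signals:
        j = snp_index.get(s.lead_id)
        if j is None:
            logger.warning("pyramiding: lead %s not in panel; dropped", s.lead_id)
            continue
        d = panel.dosages[:, j]
        means = {}
        for dose in (0, 2):
            sel = (d == dose) & ~np.isnan(y)
            if sel.sum() >= 1:
                means[dose] = y[sel].mean()
        if len(means) < 2:
            logger.warning("pyramiding: lead %s has one homozygous class; dropped", s.lead_id)
            continue
        superior_dosage[s.lead_id] = min(means, key=means.get)
    if not superior_dosage:
        raise ValueError("no usable lead SNPs for pyramiding")

    counts = np.zeros(panel.n_accessions, dtype=int)
    for sid, dose in superior_dosage.items():
        counts += (panel.dosages[:, snp_index[sid]] == dose).astype(int)
    counts_s = pd.Series(counts, index=pd.Index(panel.accession_ids, name="accession_id"))

    ok = ~np.isnan(y)
    gm = (
        pd.DataFrame({"count": counts[ok], "y": y[ok]})
        .groupby("count")["y"]
        .agg(n="size", mean="mean")
        .reset_index()
    )
    if per_accession:
        xs, ys = counts[ok].astype(float), y[ok]
    else:
        xs, ys = gm["count"].to_numpy(dtype=float), gm["mean"].to_numpy()
    if len(xs) < 2 or np.ptp(xs) == 0:
        raise ValueError("need at least two distinct superior-allele counts")
    res = stats.linregress(xs, ys)
    return PyramidResult(
        counts=counts_s, group_means=gm,
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def allele_frequency_report(
    carriers: pd.Series, populations: pd.Series, digits: int = 0
) -> pd.DataFrame:
    """Carrier frequencies by population: count, denominator, percentage.

    ``carriers`` is a boolean Series over accessions (e.g. "carries hap1" or
    "carries the A allele at the functional site"); ``populations`` maps the
    same accessions to subpopulation labels.  Populations with zero assigned
    accessions are omitted.  Percentages are rounded to ``digits`` decimals,
    matching display conventions like "23% (43 of 185 accessions)".
    """
    df = pd.DataFrame({"carrier": carriers, "pop": populations}).dropna()
    rows = []
    for pop, grp in df.groupby("pop"):
        denom = len(grp)
        if denom == 0:
            continue
        count = int(grp["carrier"].sum())
        pct = round(100.0 * count / denom, digits)
        if digits == 0:
            pct = int(pct)
        rows.append(dict(population=pop, carriers=count, n=denom, percent=pct))
    return pd.DataFrame(rows)
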