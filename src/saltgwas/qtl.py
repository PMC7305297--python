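"""From scan results to QTLs: distance merging, lead SNPs, LD-delimited
candidate regions, and gene-model overlap.

Significant SNPs (−log10 p at or above the chosen threshold) are merged per
chromosome by single-linkage chaining whenever the gap to the next significant
SNP is below ``merge_bp`` (170 kb by default, the LD-decay scale of rice
diversity panels); the member with the minimum p is the lead SNP.  Candidate
regions are then delimited by pairwise LD with the lead (r² > 0.6 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from saltgwas.calibrate import _r2_pairwise
from saltgwas.panel_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class QtlSignal:
    """A merged cluster of significant SNPs with its lead SNP."""

    chrom: str
    start: int
    end: int
    lead_id: str
    lead_pos: int
    lead_p: float
    n_snps: int
    population: str = "full"
    model: str = "GLM"

    def __post_init__(self) -> None:
        if not self.start <= self.lead_pos <= self.end:
            raise ValueError("lead SNP position outside signal span")


@dataclass
class CandidateRegion:
    """LD-delimited region around a lead SNP, optionally annotated with genes."""

    chrom: str
    start: int
    end: int
    lead_id: str
    members: pd.DataFrame  # columns: id, pos, r2
    genes: pd.DataFrame | None = None


def clump_signals(
    result: pd.DataFrame,
    threshold: float,
    merge_bp: int = 170_000,
    population: str = "full",
    model: str = "GLM",
) -> list[QtlSignal]:
    """Merge significant SNPs into association signals by genomic distance.

    SNPs with log10p >= ``threshold`` are selected; per chromosome, adjacent
    significant SNPs with an inter-SNP gap < ``merge_bp`` are chained into one
    signal.  The lead SNP is the member with minimum p (ties broken by smaller
    position).  Returns an empty list when nothing is significant.
    """
    sig = result[result["log10p"] >= threshold].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["chrom", "pos"], kind="stable")
    signals: list[QtlSignal] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= merge_bp) + 1 if merge_bp > 0 else np.arange(1, len(pos))
        for chunk in np.split(np.arange(len(pos)), breaks):
            members = grp.iloc[chunk]
            lead = members.sort_values(["p", "pos"], kind="stable").iloc[0]
            signals.append(
                QtlSignal(
                    chrom=chrom,
                    start=int(members["pos"].min()),
                    end=int(members["pos"].max()),
                    lead_id=str(lead["id"]),
                    lead_pos=int(lead["pos"]),
                    lead_p=float(lead["p"]),
                    n_snps=len(members),
                    population=population,
                    model=model,
                )
            )
    return signals


def signals_table(signals: list[QtlSignal]) -> pd.DataFrame:
    """QTL signals as a TSV-ready table."""
    rows = [
        dict(qtl=f"qSTL{s.chrom.lstrip('chr').lstrip('0') or '0'}-{i + 1}",
             chrom=s.chrom, start=s.start, end=s.end, lead_id=s.lead_id,
             lead_pos=s.lead_pos, lead_log10p=-np.log10(s.lead_p) if s.lead_p > 0 else np.inf,
             n_snps=s.n_snps, population=s.population, model=s.model)
        for i, s in enumerate(signals)
    ]
    return pd.DataFrame(rows)


def pairwise_r2(panel: GenotypePanel, snp_indices) -> pd.DataFrame:
    """Symmetric r² matrix (squared Pearson dosage correlation, pairwise-complete).

    Rows for SNPs monomorphic over the non-missing calls are reported missing.
    """
    idx = list(snp_indices)
    if len(idx) < 2:
        raise ValueError("pairwise_r2 needs at least 2 SNPs")
    ids = [panel.snps["id"].iat[j] for j in idx]
    d = panel.dosages
    k = len(idx)
    out = np.full((k, k), np.nan)
    mono = []
    for a, j in enumerate(idx):
        calls = d[d[:, j] != MISSING, j]
        if calls.size == 0 or np.ptp(calls) == 0:
            mono.append(a)
    for a in range(k):
        if a in mono:
            continue
        out[a, a] = 1.0
        for b in range(a + 1, k):
            if b in mono:
                continue
            out[a, b] = out[b, a] = _r2_pairwise(d, idx[a], idx[b])
    return pd.DataFrame(out, index=ids, columns=ids)


def candidate_region(
    panel: GenotypePanel,
    signal: QtlSignal,
    r2_min: float = 0.6,
    scan_bp: int = 500_000,
) -> CandidateRegion:
    """Delimit the candidate region around a lead SNP by LD.

    r² between the lead and every SNP within ±``scan_bp`` is computed; the
    region spans all SNPs with r² > ``r2_min`` (the lead always included).
    """
    snps = panel.snps
    lead_rows = np.flatnonzero((snps["id"] == signal.lead_id).to_numpy())
    if lead_rows.size == 0:
        raise ValueError(f"lead SNP {signal.lead_id} not in panel")
    lead = int(lead_rows[0])
    lead_calls = panel.dosages[panel.dosages[:, lead] != MISSING, lead]
    if lead_calls.size == 0 or np.ptp(lead_calls) == 0:
        raise ValueError(f"lead SNP {signal.lead_id} monomorphic in this panel")
    near = panel.snp_indices_in(signal.chrom, signal.lead_pos - scan_bp, signal.lead_pos + scan_bp)
    rows = []
    for j in near:
        r2 = 1.0 if j == lead else _r2_pairwise(panel.dosages, lead, j)
        if j == lead or r2 > r2_min:
            rows.append(dict(id=snps["id"].iat[j], pos=int(snps["pos"].iat[j]), r2=r2))
    members = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    return CandidateRegion(
        chrom=signal.chrom,
        start=int(members["pos"].min()),
        end=int(members["pos"].max()),
        lead_id=signal.lead_id,
        members=members,
    )


def read_gene_models(gff3_path: str) -> pd.DataFrame:
    """Gene intervals from a GFF3 file (type == 'gene'), 1-based inclusive."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique")
    rows = []
    for g in db.features_of_type("gene"):
        note = g.attributes.get("Note", g.attributes.get("description", [""]))
        rows.append(
            dict(chrom=g.seqid, start=g.start, end=g.end,
                 id=g.id, annotation=note[0] if note else "")
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "annotation"])


def overlap_genes(region: CandidateRegion, gene_models: pd.DataFrame) -> CandidateRegion:
    """Attach gene models intersecting the region (1-based inclusive boundaries).

    A gene touching the region at a single bp counts.  Chromosome-name
    mismatch yields zero overlaps with a warning.
    """
    same = gene_models[gene_models["chrom"] == region.chrom]
    if same.empty and not gene_models.empty:
        logger.warning(
            "overlap_genes: no gene models on %s (names present: %s)",
            region.chrom, sorted(gene_models["chrom"].unique())[:5],
        )
    hit = same[(same["end"] >= region.start) & (same["start"] <= region.end)]
    region.genes = hit.reset_index(drop=True)
    return region


def regions_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Candidate regions as 0-based half-open BED rows."""
    return pd.DataFrame(
        [dict(chrom=r.chrom, start=r.start - 1, end=r.end, name=r.lead_id) for r in regions]
    )
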