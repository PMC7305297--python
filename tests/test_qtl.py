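"""Clumping vs brute-force interval merging, LD-delimited candidate regions,
pairwise r2, and gene-model overlap."""

import numpy as np
import pandas as pd
import pytest

from saltgwas.qtl import (
    CandidateRegion,
    QtlSignal,
    candidate_region,
    clump_signals,
    overlap_genes,
    pairwise_r2,
)
from saltgwas.panel_io import MISSING
from saltgwas.syndata import SimConfig, simulate_panel

from conftest import make_panel


def _scan_frame(positions, log10p, chrom="chr01"):
    log10p = np.asarray(log10p, dtype=float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "id": [f"{chrom}_{p}" for p in positions],
            "beta": 0.0,
            "se": 1.0,
            "p": 10.0 ** (-log10p),
            "log10p": log10p,
            "maf": 0.2,
            "n": 100,
        }
    )


def test_clump_rule_example():
    """Positions 100k/200k/450k at merge 170 kb: gaps 100 kb and 250 kb -> 2 signals."""
    res = _scan_frame([100_000, 200_000, 450_000], [5, 6, 5])
    signals = clump_signals(res, threshold=4.0, merge_bp=170_000)
    assert [(s.start, s.end) for s in signals] == [(100_000, 200_000), (450_000, 450_000)]
    assert signals[0].lead_pos == 200_000  # minimum p among members
    assert signals[1].lead_pos == signals[1].start == signals[1].end


def test_clump_no_significant_and_tie_break():
    res = _scan_frame([1000, 2000], [2, 2])
    assert clump_signals(res, threshold=4.0) == []
    tie = _scan_frame([1000, 2000], [5, 5])
    s = clump_signals(tie, threshold=4.0)
    assert len(s) == 1 and s[0].lead_pos == 1000  # tie -> smaller position


def _brute_force_merge(positions, merge_bp):
    """Single-linkage chaining of sorted positions, exhaustive and independent."""
    clusters = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] < merge_bp:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return [(c[0], c[-1], len(c)) for c in clusters]


def test_clump_matches_bruteforce_merge_oracle(rng):
    for trial in range(20):
        pos = np.sort(rng.choice(np.arange(1, 5_000_000), size=50, replace=False))
        res = _scan_frame(pos, rng.uniform(4.5, 9.0, size=50))
        signals = clump_signals(res, threshold=4.0, merge_bp=170_000)
        expected = _brute_force_merge(pos, 170_000)
        assert [(s.start, s.end, s.n_snps) for s in signals] == expected
        # every significant SNP falls in exactly one signal
        covered = [p for s in signals for p in pos if s.start <= p <= s.end]
        assert sorted(covered) == sorted(pos)


def test_clump_zero_merge_and_order_invariance(rng):
    pos = np.sort(rng.choice(np.arange(1, 10**6), size=30, replace=False))
    res = _scan_frame(pos, rng.uniform(4.1, 8.0, size=30))
    singles = clump_signals(res, threshold=4.0, merge_bp=0)
    assert len(singles) == 30
    shuffled = res.sample(frac=1.0, random_state=1).reset_index(drop=True)
    s1 = clump_signals(res, 4.0)
    s2 = clump_signals(shuffled, 4.0)
    assert [(s.start, s.end) for s in s1] == [(s.start, s.end) for s in s2]


def test_pairwise_r2_trivials():
    d = np.array(
        [[0, 0, 1], [0, 0, 1], [1, 1, 0], [1, 1, 0], [2, 2, 1], [2, 2, 2]],
        dtype=np.int8,
    )
    panel = make_panel(d)
    r2 = pairwise_r2(panel, [0, 1, 2])
    assert r2.iloc[0, 1] == pytest.approx(1.0)  # duplicated columns
    # perfect negative correlation still gives r2 = 1
    d2 = np.array([[0], [0], [1], [1]], dtype=np.int8)
    neg = np.array([[1], [1], [0], [0]], dtype=np.int8)
    panel2 = make_panel(np.column_stack([d2, neg]))
    assert pairwise_r2(panel2, [0, 1]).iloc[0, 1] == pytest.approx(1.0)


def test_pairwise_r2_matches_covariance_oracle(rng):
    d = rng.integers(0, 3, size=(25, 3)).astype(np.int8)
    panel = make_panel(d)
    r2 = pairwise_r2(panel, [0, 1, 2])
    for i in range(3):
        for j in range(i + 1, 3):
            x, y = d[:, i].astype(float), d[:, j].astype(float)
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            expected = (cov / (x.std() * y.std())) ** 2
            assert r2.iloc[i, j] == pytest.approx(expected, abs=1e-10)


def test_pairwise_r2_monomorphic_row_missing():
    d = np.column_stack(
        [np.ones(10, dtype=np.int8), np.arange(10, dtype=np.int8) % 3]
    )
    r2 = pairwise_r2(make_panel(d), [0, 1])
    assert np.isnan(r2.iloc[0, 1]) and np.isnan(r2.iloc[0, 0])


def _signal_for(panel, lead_idx):
    row = panel.snps.iloc[lead_idx]
    return QtlSignal(chrom=row["chrom"], start=int(row["pos"]), end=int(row["pos"]),
                     lead_id=row["id"], lead_pos=int(row["pos"]), lead_p=1e-6, n_snps=1)


def test_candidate_region_perfect_ld_member(rng):
    base = rng.integers(0, 3, size=30).astype(np.int8)
    other = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
    d = np.column_stack([base, other[:, 0], base, other[:, 1]])
    panel = make_panel(d, positions=[1000, 2000, 3000, 4000])
    reg = candidate_region(panel, _signal_for(panel, 0), r2_min=0.6, scan_bp=10_000)
    assert "chr01_3000" in set(reg.members["id"])  # duplicated column, r2 = 1
    assert reg.members.set_index("id").at["chr01_3000", "r2"] == pytest.approx(1.0)


def test_candidate_region_independent_snps_collapse():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(120, 21)).astype(np.int8)
        panel = make_panel(d)
        reg = candidate_region(panel, _signal_for(panel, 10), r2_min=0.6, scan_bp=50_000)
        if len(reg.members) == 1:
            hits += 1
    assert hits >= 9


def test_candidate_region_matches_direct_r2(rng):
    cfg = SimConfig(n_accessions=100, subpop_fractions=(1.0, 0.0), n_chrom=1,
                    snps_per_chrom=20, chrom_length_bp=200_000,
                    ld_block_mean_bp=80_000, fst=0.0, missing_rate=0.0,
                    n_founders=8, seed=41)
    panel = simulate_panel(cfg).genotypes
    lead = 10
    reg = candidate_region(panel, _signal_for(panel, lead), r2_min=0.6, scan_bp=500_000)
    from saltgwas.calibrate import _r2_pairwise

    expected = {panel.snps["id"].iat[lead]}
    for j in range(panel.n_snps):
        if j != lead and _r2_pairwise(panel.dosages, lead, j) > 0.6:
            expected.add(panel.snps["id"].iat[j])
    assert set(reg.members["id"]) == expected


def test_candidate_region_monomorphic_lead_errors():
    d = np.column_stack([np.ones(10, dtype=np.int8), np.arange(10, dtype=np.int8) % 3])
    panel = make_panel(d)
    with pytest.raises(ValueError, match="monomorphic"):
        candidate_region(panel, _signal_for(panel, 0))


def _region(chrom="chr01", start=10_000, end=20_000):
    return CandidateRegion(chrom=chrom, start=start, end=end, lead_id="x",
                           members=pd.DataFrame({"id": ["x"], "pos": [start], "r2": [1.0]}))


def test_gene_overlap_boundaries_and_mismatch():
    genes = pd.DataFrame(
        {
            "chrom": ["chr01", "chr01", "chr01", "chr02"],
            "start": [12_000, 5_000, 21_000, 12_000],
            "end": [13_000, 10_000, 25_000, 13_000],
            "id": ["inside", "touch_start", "after", "wrong_chrom"],
            "annotation": "",
        }
    )
    reg = overlap_genes(_region(), genes)
    assert set(reg.genes["id"]) == {"inside", "touch_start"}  # inclusive boundary
    reg2 = overlap_genes(_region(chrom="chr09"), genes)
    assert len(reg2.genes) == 0


def test_gene_overlap_matches_bruteforce(rng):
    genes = pd.DataFrame(
        {
            "chrom": "chr01",
            "start": rng.integers(1, 50_000, size=10),
            "id": [f"g{i}" for i in range(10)],
            "annotation": "",
        }
    )
    genes["end"] = genes["start"] + rng.integers(100, 20_000, size=10)
    reg = overlap_genes(_region(start=15_000, end=30_000), genes)
    expected = {
        r.id for r in genes.itertuples() if r.end >= 15_000 and r.start <= 30_000
    }
    assert set(reg.genes["id"]) == expected


def test_gff3_reader(tmp_path):
    from saltgwas.qtl import read_gene_models

    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr01\ttest\tgene\t100\t500\t.\t+\t.\tID=LOC_Os01g01010;Note=zinc finger\n"
        "chr01\ttest\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=LOC_Os01g01010\n"
        "chr02\ttest\tgene\t900\t1200\t.\t-\t.\tID=LOC_Os02g02020\n"
    )
    genes = read_gene_models(str(gff))
    assert len(genes) == 2
    assert genes.set_index("id").at["LOC_Os01g01010", "annotation"] == "zinc finger"
    assert genes.set_index("id").at["LOC_Os02g02020", "end"] == 1200
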