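"""Haplotype grouping, Welch/ANOVA + Duncan letters against a hand-executed
multiple-range oracle, combination haplotypes, pyramiding, allele frequencies."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saltgwas.hapstats import (
    allele_frequency_report,
    build_haplotypes,
    combine_haplotypes,
    compare_haplotypes,
    duncan_letters,
    pyramiding,
)
from saltgwas.panel_io import MISSING
from saltgwas.qtl import CandidateRegion, QtlSignal

from conftest import make_panel


def _region_scan(panel, log10p):
    members = pd.DataFrame(
        {"id": panel.snps["id"], "pos": panel.snps["pos"], "r2": 1.0}
    )
    region = CandidateRegion(chrom="chr01", start=int(panel.snps["pos"].min()),
                             end=int(panel.snps["pos"].max()),
                             lead_id=panel.snps["id"].iat[0], members=members)
    scan = pd.DataFrame(
        {"id": panel.snps["id"], "log10p": log10p, "p": 10.0 ** -np.asarray(log10p)}
    )
    return region, scan


def test_haplotype_grouping_and_het_unassigned():
    """Alleles G/A and C/T at 2 sites; {GC, GC, AT} -> groups of 2 and 1;
    a heterozygous accession is unassigned."""
    d = np.array([[0, 0], [0, 0], [2, 2], [1, 0]], dtype=np.int8)
    panel = make_panel(d, ref="G", alt="A")
    panel.snps.loc[1, "ref"], panel.snps.loc[1, "alt"] = "C", "T"
    region, scan = _region_scan(panel, [3.0, 3.0])
    ann = {panel.snps["id"].iat[0]: "nonsynonymous", panel.snps["id"].iat[1]: "nonsynonymous"}
    table = build_haplotypes(panel, region, scan, ann, min_logp=2.0, min_group=1)
    strings = table.groups.set_index("hap")["allele_string"]
    assert strings["hap1"] == "GC" and strings["hap2"] == "AT"
    assert table.groups.set_index("hap")["n"].to_dict() == {"hap1": 2, "hap2": 1}
    assert pd.isna(table.assignments.iloc[3])  # heterozygous -> unassigned


def test_site_selection_rules():
    """Nonsynonymous need -log10 p > 2; promoter SNPs need genome-wide significance."""
    d = np.array([[0, 0, 0, 0], [2, 2, 2, 2], [0, 2, 0, 2]], dtype=np.int8)
    panel = make_panel(d)
    ids = list(panel.snps["id"])
    region, scan = _region_scan(panel, [2.5, 1.5, 5.0, 3.0])
    ann = {ids[0]: "nonsynonymous", ids[1]: "nonsynonymous",
           ids[2]: "promoter", ids[3]: "promoter"}
    table = build_haplotypes(panel, region, scan, ann, min_logp=2.0,
                             promoter_logp=4.0, min_group=1)
    assert list(table.sites["id"]) == [ids[0], ids[2]]
    with pytest.raises(ValueError, match="no qualifying"):
        build_haplotypes(panel, region, scan, {i: "other" for i in ids}, min_group=1)


def test_four_site_two_haplotype_structure():
    """One nonsynonymous + three promoter SNPs in full LD yield two haplotypes."""
    rng = np.random.default_rng(6)
    carrier = rng.random(120) < 0.3
    col = np.where(carrier, 2, 0).astype(np.int8)
    d = np.tile(col[:, None], (1, 4))
    panel = make_panel(d, ref="G", alt="A")
    ids = list(panel.snps["id"])
    region, scan = _region_scan(panel, [3.0, 5.0, 5.0, 5.0])
    ann = {ids[0]: "nonsynonymous", ids[1]: "promoter", ids[2]: "promoter", ids[3]: "promoter"}
    table = build_haplotypes(panel, region, scan, ann, min_logp=2.0, min_group=10)
    named = table.groups[table.groups["hap"] != "rare"]
    assert len(table.sites) == 4
    assert len(named) == 2


def test_rare_pooling():
    d = np.zeros((30, 1), dtype=np.int8)
    d[:3, 0] = 2  # 3 carriers < min_group
    panel = make_panel(d)
    region, scan = _region_scan(panel, [3.0])
    table = build_haplotypes(panel, region, scan,
                             {panel.snps["id"].iat[0]: "nonsynonymous"}, min_group=10)
    assert set(table.assignments.dropna().unique()) == {"hap1", "rare"}
    assert (table.assigned() == "hap1").sum() == 27


# ---------------------------------------------------------------------------
# Group comparisons and Duncan letters
# ---------------------------------------------------------------------------

def _pheno_frame(groups: dict[str, np.ndarray], subpop="indica"):
    rows = []
    i = 0
    for hap, vals in groups.items():
        for v in vals:
            rows.append(dict(accession_id=f"a{i}", subpop=subpop, STL=v, hap=hap))
            i += 1
    return pd.DataFrame(rows)


def _table_from_assignments(df):
    from saltgwas.hapstats import HaplotypeTable

    assign = pd.Series(df["hap"].to_numpy(), index=pd.Index(df["accession_id"], name="accession_id"), dtype=object)
    groups = df.groupby("hap").size().reset_index(name="n")
    groups["allele_string"] = "?"
    return HaplotypeTable(region_id="toy", sites=pd.DataFrame(), assignments=assign, groups=groups)


def test_null_groups_share_letter(rng):
    vals = rng.normal(5, 1.5, size=60)
    df = _pheno_frame({"hap1": vals[:30], "hap2": vals[30:]})
    res = compare_haplotypes(_table_from_assignments(df), df, alpha=0.01)["indica"]
    assert res.p > 0.01
    assert set(res.stats["letter"]) == {"a"}


def test_group_sizes_at_reported_scale_are_separable(rng):
    """Means 4.5 vs 5.4 (SD 1.5) at n = 43 and 142 are detectably different at
    alpha = 0.01; verified against the direct Welch t oracle."""
    g1 = rng.normal(0, 1, 43)
    g1 = 4.5 + 1.5 * (g1 - g1.mean()) / g1.std(ddof=1)
    g2 = rng.normal(0, 1, 142)
    g2 = 5.4 + 1.5 * (g2 - g2.mean()) / g2.std(ddof=1)
    df = _pheno_frame({"hap1": g1, "hap2": g2})
    res = compare_haplotypes(_table_from_assignments(df), df, alpha=0.01)["indica"]
    # independent Welch oracle from the closed-form statistic
    se = np.sqrt(1.5**2 / 43 + 1.5**2 / 142)
    t = (4.5 - 5.4) / se
    dfree = se**4 / ((1.5**2 / 43) ** 2 / 42 + (1.5**2 / 142) ** 2 / 141)
    p_oracle = 2 * stats.t.sf(abs(t), dfree)
    assert res.p == pytest.approx(p_oracle, rel=1e-6)
    assert p_oracle < 0.01
    letters = res.stats.set_index("hap")["letter"]
    assert letters["hap1"] != letters["hap2"]
    assert res.superior == "hap1"  # lower mean STL = more tolerant


def _duncan_oracle(means, ns, mse, df_err, alpha):
    """Hand-executed multiple range procedure: sort means, test ranges from the
    widest down, never declaring differences inside a non-significant range."""
    k = len(means)
    order = np.argsort(means)
    sm = np.asarray(means)[order]
    n_h = k / np.sum(1.0 / np.asarray(ns, dtype=float))
    protected = np.zeros((k, k), dtype=bool)  # [i,j]: declared NOT different
    for span in range(k, 1, -1):
        alpha_p = 1 - (1 - alpha) ** (span - 1)
        rp = stats.studentized_range.ppf(1 - alpha_p, span, df_err) * np.sqrt(mse / n_h)
        for i in range(k - span + 1):
            j = i + span - 1
            if protected[i, j]:
                continue
            if sm[j] - sm[i] <= rp:
                protected[i:j + 1, i:j + 1] = True
    # letters: maximal diagonal blocks of the protected matrix
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and protected[i, j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in runs):
            runs.append((i, j))
    letters_sorted = ["" for _ in range(k)]
    for li, (a, b) in enumerate(runs):
        for g in range(a, b + 1):
            letters_sorted[g] += chr(ord("a") + li)
    out = ["" for _ in range(k)]
    for pos, orig in enumerate(order):
        out[orig] = letters_sorted[pos]
    return out


@pytest.mark.parametrize("shift", [3.0, 1.2, 0.8])
def test_duncan_letters_match_stepwise_oracle(rng, shift):
    """Three groups with one shifted mean: letters equal the hand-executed
    multiple-range procedure on the same inputs."""
    groups = {
        "hap1": rng.normal(5.0, 1.0, 40),
        "hap2": rng.normal(5.1, 1.0, 35),
        "hap3": rng.normal(5.0 + shift, 1.0, 30),
    }
    arrays = list(groups.values())
    means = np.array([a.mean() for a in arrays])
    ns = np.array([len(a) for a in arrays])
    df_err = sum(ns) - 3
    mse = sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / df_err
    got = duncan_letters(means, ns, mse, df_err, alpha=0.01)
    expected = _duncan_oracle(means, ns, mse, df_err, alpha=0.01)
    assert got == expected


def test_duncan_letter_transitivity(rng):
    """All pairs sharing a letter are pairwise non-significant by the range test."""
    groups = [rng.normal(mu, 1.0, 30) for mu in (5.0, 5.3, 5.6, 7.0)]
    means = np.array([a.mean() for a in groups])
    ns = np.array([len(a) for a in groups])
    df_err = sum(ns) - 4
    mse = sum((len(a) - 1) * a.var(ddof=1) for a in groups) / df_err
    letters = duncan_letters(means, ns, mse, df_err, alpha=0.05)
    n_h = 4 / np.sum(1.0 / ns)
    order = np.argsort(means)
    rank = {g: r for r, g in enumerate(order)}
    for i in range(4):
        for j in range(i + 1, 4):
            if set(letters[i]) & set(letters[j]):
                span = abs(rank[i] - rank[j]) + 1
                alpha_p = 1 - (1 - 0.05) ** (span - 1)
                rp = stats.studentized_range.ppf(1 - alpha_p, span, df_err) * np.sqrt(mse / n_h)
                # non-significant directly, or protected inside a wider
                # non-significant range — either way the difference cannot
                # exceed the full-range critical value
                alpha_k = 1 - (1 - 0.05) ** 3
                rk = stats.studentized_range.ppf(1 - alpha_k, 4, df_err) * np.sqrt(mse / n_h)
                assert abs(means[i] - means[j]) <= max(rp, rk)


# ---------------------------------------------------------------------------
# Combinations and pyramiding
# ---------------------------------------------------------------------------

def _hap_table(assign_dict, region_id):
    from saltgwas.hapstats import HaplotypeTable

    assign = pd.Series(assign_dict, dtype=object)
    assign.index.name = "accession_id"
    groups = pd.Series(assign_dict).value_counts().rename_axis("hap").reset_index(name="n")
    groups["allele_string"] = "?"
    return HaplotypeTable(region_id=region_id, sites=pd.DataFrame(), assignments=assign, groups=groups)


def test_combine_two_by_three_cross(rng):
    n = 240
    acc = [f"a{i}" for i in range(n)]
    h1 = rng.choice(["hap1", "hap2"], size=n)
    h2 = rng.choice(["hap1", "hap2", "hap3"], size=n)
    eff1 = np.where(h1 == "hap1", -0.6, 0.6)
    eff2 = {"hap1": -0.6, "hap2": -0.5, "hap3": 0.8}
    y = 5 + eff1 + np.array([eff2[h] for h in h2]) + rng.normal(0, 0.5, n)
    pheno = pd.DataFrame({"accession_id": acc, "subpop": "indica", "STL": y})
    t1 = _hap_table(dict(zip(acc, h1)), "gene1")
    t2 = _hap_table(dict(zip(acc, h2)), "gene2")
    combo = combine_haplotypes(t1, t2, pheno, alpha=0.05)
    assert len(combo.combos) == 6
    assert list(combo.combos["co_hap"]) == [f"co-hap{i}" for i in range(1, 7)]
    # additive truth: the individually best pair has the lowest combination mean
    best = combo.combos.sort_values("mean").iloc[0]
    assert (best["hap1"], best["hap2"]) == ("hap1", "hap1")
    assert best["class"] == "superior"
    worst = combo.combos.sort_values("mean").iloc[-1]
    assert (worst["hap1"], worst["hap2"]) == ("hap2", "hap3")
    assert worst["class"] == "inferior"


def test_combine_degenerate_single_haplotype(rng):
    n = 60
    acc = [f"a{i}" for i in range(n)]
    h1 = ["hap1"] * n
    h2 = rng.choice(["hap1", "hap2"], size=n)
    y = 5 + np.where(h2 == "hap1", -1.0, 1.0) + rng.normal(0, 0.5, n)
    pheno = pd.DataFrame({"accession_id": acc, "subpop": "indica", "STL": y})
    combo = combine_haplotypes(_hap_table(dict(zip(acc, h1)), "g1"),
                               _hap_table(dict(zip(acc, h2)), "g2"), pheno)
    assert len(combo.combos) == 2  # collapses to the second gene's groups


def _panel_with_leads(rng, n, dosage_cols):
    d = np.column_stack(dosage_cols).astype(np.int8)
    return make_panel(d, positions=(np.arange(d.shape[1]) + 1) * 1_000_000)


def _signals_for_all(panel):
    return [
        QtlSignal(chrom="chr01", start=int(p), end=int(p), lead_id=i, lead_pos=int(p),
                  lead_p=1e-8, n_snps=1)
        for i, p in zip(panel.snps["id"], panel.snps["pos"])
    ]


def test_pyramiding_single_lead_degenerate(rng):
    col = rng.choice([0, 2], size=50)
    panel = _panel_with_leads(rng, 50, [col])
    y = 5 - (col == 2) * 1.0 + rng.normal(0, 0.3, 50)
    pheno = pd.DataFrame({"accession_id": panel.accession_ids, "STL": y})
    res = pyramiding(panel, _signals_for_all(panel), pheno)
    assert set(res.counts.unique()) <= {0, 1}
    assert res.r2 == pytest.approx(1.0)  # two group means, exact line


def test_pyramiding_r2_matches_least_squares_oracle(rng):
    cols = [rng.choice([0, 2], size=20) for _ in range(3)]
    panel = _panel_with_leads(rng, 20, cols)
    y = 5.0 + rng.normal(0, 1.0, 20)
    pheno = pd.DataFrame({"accession_id": panel.accession_ids, "STL": y})
    res = pyramiding(panel, _signals_for_all(panel), pheno)
    gm = res.group_means
    x, m = gm["count"].to_numpy(dtype=float), gm["mean"].to_numpy()
    slope = np.sum((x - x.mean()) * (m - m.mean())) / np.sum((x - x.mean()) ** 2)
    inter = m.mean() - slope * x.mean()
    ss_res = np.sum((m - inter - slope * x) ** 2)
    ss_tot = np.sum((m - m.mean()) ** 2)
    assert res.slope == pytest.approx(slope, abs=1e-10)
    assert res.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
    assert 0.0 <= res.r2 <= 1.0


def test_pyramiding_invariant_to_signal_order(rng):
    cols = [rng.choice([0, 1, 2], size=40) for _ in range(4)]
    panel = _panel_with_leads(rng, 40, cols)
    y = 5 - 0.5 * sum((c == 2).astype(float) for c in cols) + rng.normal(0, 0.5, 40)
    pheno = pd.DataFrame({"accession_id": panel.accession_ids, "STL": y})
    sigs = _signals_for_all(panel)
    r1 = pyramiding(panel, sigs, pheno)
    r2 = pyramiding(panel, sigs[::-1], pheno)
    assert r1.counts.equals(r2.counts)


def test_pyramiding_monomorphic_lead_dropped(rng):
    cols = [np.full(30, 2), rng.choice([0, 2], size=30)]
    panel = _panel_with_leads(rng, 30, cols)
    y = rng.normal(5, 1, 30)
    pheno = pd.DataFrame({"accession_id": panel.accession_ids, "STL": y})
    res = pyramiding(panel, _signals_for_all(panel), pheno)
    assert res.counts.max() <= 1  # only the polymorphic lead counts


def test_allele_frequency_report_printed_example():
    """43 carriers of 185 -> 23%; the complement 142 of 185 -> 77%."""
    carriers = pd.Series([True] * 43 + [False] * 142,
                         index=[f"a{i}" for i in range(185)])
    pops = pd.Series(["japonica"] * 185, index=carriers.index)
    rep = allele_frequency_report(carriers, pops).set_index("population")
    assert rep.at["japonica", "carriers"] == 43
    assert rep.at["japonica", "n"] == 185
    assert rep.at["japonica", "percent"] == 23
    comp = allele_frequency_report(~carriers, pops).set_index("population")
    assert comp.at["japonica", "percent"] == 77
    zero = allele_frequency_report(pd.Series(False, index=carriers.index), pops)
    assert zero["percent"].iloc[0] == 0
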