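"""End-to-end pipeline: QC → structure → scans → calibration → QTLs →
haplotypes → pyramiding → diversity, with a machine-readable run manifest.

The pipeline is a pure function of (inputs, config, seeds): rerunning with the
same config and input files reproduces every output table byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import saltgwas
from saltgwas import assoc, calibrate, diversity, hapstats, panel_io, qtl, structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full run.  Mirrors the YAML schema 1:1."""

    vcf: str
    phenotypes: str
    gff3: str | None = None
    out_dir: str = "saltgwas_out"
    populations: tuple[str, ...] = ("full",)
    models: tuple[str, ...] = ("GLM", "MLM")
    trait: str = "STL"
    max_missing: float = 0.30
    min_maf: float = 0.05
    n_pcs: int = 3
    threshold_mode: str = "fixed"  # fixed | formula | permutation
    fixed_threshold: float = 4.0
    n_perm: int = 1000
    perm_alpha: float = 0.05
    merge_bp: int = 170_000
    r2_min: float = 0.6
    scan_bp: int = 500_000
    hap_min_logp: float = 2.0
    hap_min_group: int = 10
    nj_max_snps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations or not self.models:
            raise ValueError("at least one population and one model required")
        if self.threshold_mode not in ("fixed", "formula", "permutation"):
            raise ValueError("threshold_mode must be fixed, formula or permutation")
        for m in self.models:
            if m not in ("GLM", "MLM"):
                raise ValueError(f"unknown model {m}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("populations", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON).

    Stages whose preconditions are unmet on this input (e.g. no significant
    SNPs to clump, or fewer than two signals for pyramiding) are recorded in
    the manifest as skipped with a reason; a stage failure aborts with the
    stage name, keeping partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": saltgwas.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }
    stages = manifest["stages"]

    def done(name: str, **info) -> None:
        stages[name] = {"status": "complete", **info}
        logger.info("stage %s: complete %s", name, info or "")

    def skipped(name: str, reason: str) -> None:
        stages[name] = {"status": "skipped", "reason": reason}
        logger.info("stage %s: skipped (%s)", name, reason)

    current = "read"
    try:
        panel_all, pheno_all = panel_io.read_panel(config.vcf, config.phenotypes)
        done("read", n_accessions=panel_all.n_accessions, n_snps=panel_all.n_snps)

        current = "descriptives"
        summ = panel_io.trait_summary(pheno_all, by_subpop=True)
        _write(summ, out / "trait_summary.tsv")
        r, p = panel_io.trait_correlations(pheno_all)
        r.to_csv(out / "trait_correlations_r.tsv", sep="\t", float_format="%.6g")
        p.to_csv(out / "trait_correlations_p.tsv", sep="\t", float_format="%.6g")
        done("descriptives", rows=len(summ))

        gene_models = None
        if config.gff3:
            gene_models = qtl.read_gene_models(config.gff3)

        all_signals: dict[str, list[qtl.QtlSignal]] = {}
        region_tables: list[hapstats.HaplotypeTable] = []
        pheno_by_pop: dict[str, pd.DataFrame] = {}
        panel_by_pop: dict[str, panel_io.GenotypePanel] = {}
        scan_by_pop: dict[str, pd.DataFrame] = {}

        for pop in config.populations:
            tag = pop
            if pop == "full":
                acc_idx = np.arange(panel_all.n_accessions)
            else:
                acc_idx = np.flatnonzero((pheno_all["subpop"] == pop).to_numpy())
                if acc_idx.size == 0:
                    skipped(f"population:{tag}", f"no accessions labeled {pop}")
                    continue
            sub_pheno = pheno_all.iloc[acc_idx].reset_index(drop=True)

            current = f"qc:{tag}"
            panel = panel_io.filter_snps(
                panel_all.subset(accessions=acc_idx),
                max_missing=config.max_missing, min_maf=config.min_maf,
            )
            if panel.n_snps == 0:
                skipped(current, "all SNPs removed by QC")
                continue
            done(current, n_snps=panel.n_snps)
            pheno_by_pop[pop] = sub_pheno
            panel_by_pop[pop] = panel

            current = f"structure:{tag}"
            pcs = structure.compute_pca(panel, k=max(config.n_pcs, 1))
            pd.DataFrame(
                pcs.scores, index=panel.accession_ids,
                columns=[f"PC{i+1}" for i in range(pcs.scores.shape[1])],
            ).to_csv(out / f"pcs_{tag}.tsv", sep="\t", float_format="%.6g")
            K = structure.compute_kinship(panel)
            pd.DataFrame(K, index=panel.accession_ids, columns=panel.accession_ids).to_csv(
                out / f"kinship_{tag}.tsv", sep="\t", float_format="%.6g"
            )
            tree = structure.neighbor_joining(panel, max_snps=config.nj_max_snps)
            tree.write(str(out / f"nj_{tag}.nwk"))
            done(current, pc1_variance=float(pcs.variance_explained[0]))

            current = f"threshold:{tag}"
            y = sub_pheno[config.trait].to_numpy(dtype=float)
            neff = calibrate.ld_prune_neff(panel, population=pop)
            if config.threshold_mode == "fixed":
                threshold = config.fixed_threshold
            elif config.threshold_mode == "formula":
                threshold = calibrate.suggestive_threshold(neff)
            else:
                perm = calibrate.conditional_permutation_threshold(
                    panel, y, pcs, n_perm=config.n_perm, alpha=config.perm_alpha,
                    seed=config.seed, n_pcs=config.n_pcs,
                )
                perm.to_json(str(out / f"threshold_{tag}.json"), population=pop, neff=neff.neff)
                threshold = perm.threshold
            with open(out / f"neff_{tag}.json", "w") as fh:
                json.dump({"population": pop, "neff": neff.neff,
                           "formula_threshold": calibrate.suggestive_threshold(neff),
                           "threshold_used": threshold,
                           "mode": config.threshold_mode}, fh, indent=1)
            done(current, neff=neff.neff, threshold=threshold)

            for model in config.models:
                current = f"scan:{tag}:{model}"
                spec = assoc.ModelSpec(model=model, n_pcs=config.n_pcs, population=pop)
                if model == "GLM":
                    res = assoc.glm_scan(panel, y, pcs, spec)
                else:
                    res = assoc.mlm_scan(panel, y, pcs, K, spec)
                _write(res, out / f"scan_{tag}_{model}.tsv")
                lam = assoc.genomic_inflation(res) if res["p"].notna().sum() >= 100 else None
                done(current, genomic_inflation=lam)
                if model == config.models[-1]:
                    scan_by_pop[pop] = res

                current = f"clump:{tag}:{model}"
                signals = qtl.clump_signals(
                    res, threshold, merge_bp=config.merge_bp, population=pop, model=model
                )
                _write(qtl.signals_table(signals), out / f"qtl_{tag}_{model}.tsv")
                done(current, n_signals=len(signals))
                all_signals[f"{tag}:{model}"] = signals

                if pop == "full" and model == config.models[-1]:
                    current = f"regions:{tag}:{model}"
                    regions = []
                    for s in signals:
                        try:
                            reg = qtl.candidate_region(
                                panel, s, r2_min=config.r2_min, scan_bp=config.scan_bp
                            )
                        except ValueError as e:
                            logger.warning("candidate_region %s: %s", s.lead_id, e)
                            continue
                        if gene_models is not None:
                            reg = qtl.overlap_genes(reg, gene_models)
                        regions.append(reg)
                    if regions:
                        _write(qtl.regions_bed(regions), out / f"regions_{tag}.bed")
                        done(current, n_regions=len(regions))
                    else:
                        skipped(current, "no candidate regions")

                    current = f"haplotypes:{tag}"
                    # without functional annotation, treat region members above
                    # the haplotype log-p cutoff as the candidate site set
                    for ri, reg in enumerate(regions[:4]):
                        ann = {sid: "nonsynonymous" for sid in reg.members["id"]}
                        try:
                            table = hapstats.build_haplotypes(
                                panel, reg, res, ann,
                                min_logp=config.hap_min_logp,
                                min_group=config.hap_min_group,
                                region_id=f"region{ri+1}",
                            )
                        except ValueError as e:
                            logger.warning("haplotypes region%d: %s", ri + 1, e)
                            continue
                        region_tables.append(table)
                        tests = hapstats.compare_haplotypes(table, sub_pheno, trait=config.trait)
                        rows = []
                        for p_, t_ in tests.items():
                            df = t_.stats.copy()
                            df.insert(0, "population", p_)
                            df["anova_p"] = t_.p
                            rows.append(df)
                        if rows:
                            _write(pd.concat(rows), out / f"haplotype_tests_region{ri+1}.tsv")
                    if region_tables:
                        done(current, n_regions_haplotyped=len(region_tables))
                    else:
                        skipped(current, "no haplotype tables (no qualifying sites)")

        current = "combos"
        if len(region_tables) >= 2:
            try:
                combo = hapstats.combine_haplotypes(
                    region_tables[0], region_tables[1], pheno_by_pop.get("full", pheno_all)
                )
                _write(combo.combos, out / "combo_haplotypes.tsv")
                done(current, n_combos=len(combo.combos))
            except ValueError as e:
                skipped(current, str(e))
        else:
            skipped(current, "fewer than two haplotyped regions")

        current = "pyramiding"
        key = next((k for k in all_signals if k.startswith("full:")), None)
        signals = all_signals.get(key, []) if key else []
        if len(signals) >= 2 and "full" in panel_by_pop:
            try:
                pyr = hapstats.pyramiding(
                    panel_by_pop["full"], signals, pheno_by_pop["full"], trait=config.trait
                )
                _write(pyr.group_means.assign(slope=pyr.slope, r2=pyr.r2),
                       out / "pyramiding.tsv")
                done(current, slope=pyr.slope, r2=pyr.r2)
            except ValueError as e:
                skipped(current, str(e))
        else:
            skipped(current, "fewer than two signals in the full population")

        current = "diversity"
        div_rows = []
        if "full" in panel_by_pop and key and all_signals.get(key):
            panel = panel_by_pop["full"]
            pheno = pheno_by_pop["full"]
            for si, s in enumerate(all_signals[key][:4]):
                idx = panel.snp_indices_in(s.chrom, s.start - 2000, s.end + 2000)
                if idx.size == 0:
                    continue
                for pop in sorted(pheno["subpop"].unique()):
                    acc = np.flatnonzero((pheno["subpop"] == pop).to_numpy())
                    if acc.size < 4:
                        continue
                    sub = panel.subset(accessions=acc)
                    try:
                        st = diversity.tajimas_d(sub, idx, population=pop,
                                                 region_id=f"region{si+1}")
                    except ValueError:
                        continue
                    div_rows.append(vars(st))
        if div_rows:
            _write(pd.DataFrame(div_rows), out / "diversity.tsv")
            done(current, rows=len(div_rows))
        else:
            skipped(current, "no regions/populations eligible")

    except Exception as e:
        manifest["aborted_stage"] = current
        manifest["error"] = str(e)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise RuntimeError(f"pipeline aborted at stage {current}: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
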