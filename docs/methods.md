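# Methods

This note documents the models behind `saltgwas`, the defaults and why they
were chosen, what the synthetic panels do and do not emulate, and the
numerical choices a maintainer would want to know.

## The synthetic panel generator

The generator (`syndata`) produces diploid biallelic SNP panels with the
statistical structure the downstream analyses assume.

**Divergence.** Ancestral allele frequencies are uniform on
[`maf_min`, 1 − `maf_min`]; the two subpopulation frequencies are drawn from
the Balding–Nichols beta model
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) at the configured Fst.  The default
Fst = 0.3 produces an *indica*/*japonica*-scale split: PC1 separates the two
groups cleanly and explains a dominant share of genotypic variance.  The
realized in-sample Fst tracks the parameter but drifts per SNP — a SNP can
come out rare or even monomorphic after divergence, exactly as in real
panels.

**Linkage disequilibrium.** Within each subpopulation a pool of founder
haplotypes (default 30) carries independent Bernoulli(p_k) alleles; each
accession receives two haplotypes assembled by copying founders in contiguous
blocks of exponentially distributed length, mean `ld_block_mean_bp`
(default 170 kb, the decay scale reported for rice diversity panels).  SNPs
in one block are strongly correlated through founder sharing; r² decays to
the panmictic baseline across blocks.  Setting `ld_block_mean_bp = 0` picks
an independent founder per SNP, giving mutually independent markers — the
configuration used for calibration experiments whose test statistics assume
independence.  Because the two haplotypes are drawn independently, genotypes
are in Hardy–Weinberg proportions within subpopulations.

**Phenotype.** The liability is Σ effect·dosage + offset·1{subpop 2} +
N(0, noise_sd); a missing genotype at a causal SNP contributes its
expectation 2p.  STL (salt tolerance level) is the liability cut into nine
equal-width bins over its observed range, giving the ordinal 1–9 damage
score; six auxiliary seedling traits (shoot/root lengths and weights) are
correlated Gaussian noise sharing a latent vigor factor that is weakly and
negatively coupled to the liability, so descriptive-statistics and
trait-correlation stages have realistic input.  Defaults mirror a
664-accession panel with a 428/236 subpopulation split.

**What is not emulated.** No coalescent demography, no recombination-rate or
mutation-rate heterogeneity, no genotyping-error model, no selection, and no
polygenic background beyond the explicitly planted SNPs.  Consequently,
passing tests show the *machinery* behaves correctly under controlled
conditions (calibrated nulls, recoverable planted effects); they do not show
field performance on real panels, where unmodeled confounding (kinship
gradients, assay batch effects) is the dominant difficulty.

## Association models

The GLM is per-SNP OLS of the trait on [1, dosage, PC1..PCk]; accessions with
a missing dosage are dropped for that SNP.  STL is treated as continuous,
matching standard practice for ordinal damage scores in GWAS.  The MLM is the
EMMAX construction: kinship K (VanRaden centered GRM, ZZ′/m over standardized
dosages, missing mean-imputed) is eigendecomposed once; the variance ratio
δ = σ²_e/σ²_g is REML-estimated under the no-SNP null by a 100-point grid on
log δ ∈ [−10, 10] followed by bounded refinement to 1e-6; every SNP is then
tested by GLS at that fixed δ.  Missing dosages are mean-imputed (the rotated
design must stay aligned across SNPs).  An `exact` flag re-optimizes δ per
SNP; on simulated panels the two modes agree within ~10% on −log10 p for
non-extreme SNPs.  Individual-compression (CMLM-style clustering of
accessions) is deliberately not implemented: a full-kinship MLM detects
essentially the same loci and is simpler to reason about.

The genomic-inflation factor is λ = median(χ²₁ quantiles of observed p) /
median(χ²₁) and requires ≥100 finite p-values.

## Significance thresholds

`ld_prune_neff` mirrors PLINK's variant-count pruning: windows of 50 SNPs
advancing by 50; within a window, for any pair with r² ≥ 0.2 the
later-position SNP is removed (PLINK's exact tie-breaking is not reproduced
bit-for-bit; the effective count is insensitive to it).  r² is the squared
Pearson correlation of dosages over pairwise-complete accessions (composite
LD, no phasing).  The suggestive threshold is −log10(1/N_eff) = log10(N_eff).

The conditional permutation threshold fits Y on [1, PCs], keeps the fitted
structure component P fixed, permutes the residual G across accessions,
rescans Y* = P + G_perm with the same PC matrix, and records the genome-wide
minimum p per permutation.  The threshold is −log10 of the α-quantile
(α = 0.05, linear interpolation) of those minima — the Churchill–Doerge
family-wise construction conditioned on structure.  With no structure this
reduces to plain phenotype permutation; a fixed threshold (default 4.0) is
available as a config override for comparability with rice GWAS practice.

## QTL definition

Significant SNPs chain into one signal whenever the gap to the next
significant SNP is < 170 kb (single-linkage, so a cluster may span more than
170 kb in total — matching how multi-SNP QTLs are reported); merge distance 0
degenerates to one signal per SNP.  Lead-SNP ties on p break toward the
smaller position.  Candidate regions span all SNPs with r² > 0.6 to the lead
within a ±500 kb search radius (the radius is a package default; reported
rice candidate regions are ~0.1 Mb, well inside it).  Gene overlap is
any-intersection on 1-based inclusive coordinates, so a gene touching the
region boundary at one bp counts.

## Haplotype statistics

Haplotype sites are nonsynonymous SNPs with −log10 p > 2 plus promoter SNPs
at genome-wide significance.  Accessions heterozygous or missing at any site
are unassigned: rice diversity panels are essentially inbred, so heterozygous
calls at candidate sites are treated as unreliable rather than phased.
Groups under 10 accessions pool as "rare" and are excluded from tests (the
cutoff keeps group means estimable; published analyses report only major
haplotypes without stating one).  Two groups are compared by Welch's t, three
or more by one-way ANOVA; when the omnibus test is significant, Duncan's
multiple range test assigns compact letters using studentized-range critical
values at the Duncan protection level α_p = 1 − (1−α)^(p−1) and the
harmonic-mean group size for unbalanced designs.  "Superior" always means
minimum mean STL.  Combination haplotypes cross-classify two genes'
assignments (labels co-hap1..K in lexical order), tested at α = 0.05; a
combination carrying only the best letter is superior, only the worst letter
inferior, otherwise intermediate.

Pyramiding defines, per lead SNP, the superior allele as the homozygous
class with lower mean STL, counts homozygous-superior leads per accession,
and by default regresses *per-count group means* on the count (matching the
high reported R² convention of breeding summaries); per-accession regression
is available via a flag since the aggregation level is a genuine reporting
choice.

## Diversity statistics

Accessions are haploid-coded (heterozygous calls excluded per site).
π = Σ_sites 2p̂q̂·n_s/(n_s−1)/L with n_s the per-site usable sequence count;
L defaults to the number of usable sites, so invariant SNP records in a
region count toward L but flanking sequence does not — π's absolute scale
therefore depends on how the region's site set is assembled, while the
π-ratios and D used by the selection rules are insensitive to L.  Tajima's D
uses the canonical constants with n = the number of accessions in the
population; with missing data this is approximate (per-site n only adjusts
π), exact on complete alignments.  Selection calls: π_ref/π_focal > 2 with
focal D < 0 → positive selection; π_focal/π_ref > 2 with focal D above the
upper significance bound → balancing selection; else none.  The D bounds
default to (−1.8, 2.0), approximating Tajima's beta-distribution 5% limits
for moderate n, and are configurable.

## Calibration experiments

The standing experiments (`experiments`) use desk-scale replicates — 2,000
SNPs and 300–500 accessions — chosen as the smallest sizes at which the
tested operating characteristics are stable:

* **Type-I uniformity**: null panmictic panels with independent markers
  (`ld_block_mean_bp = 0`, large founder pool) so the Kolmogorov–Smirnov
  test's independence assumption holds; the ordinal binning of STL leaves
  the per-SNP t-test p-values indistinguishable from uniform at n = 300.
* **Structure correction**: Fst 0.3 panels with a subpopulation phenotype
  offset and no causal SNPs, scanned *without* PC covariates by both models.
  The comparison isolates what the kinship random effect absorbs: with PCs
  included, PC1 alone fully corrects this two-population scenario and both
  models tie at λ ≈ 1, which demonstrates nothing about the mixed model.
* **Permutation calibration**: on an unstructured null panel the conditional
  threshold must match naive phenotype permutation within the Monte-Carlo
  envelope of the α order statistic, and fresh null scans must exceed the
  threshold at rate α.
* **Parameter recovery**: the planted SNP's effect is rescaled per replicate
  to b = √(h²/(1−h²))/√(2p̂q̂) at its *realized* frequency so the replicate
  actually has h² ≈ 0.3 (Balding–Nichols drift otherwise spreads the realized
  heritability widely, occasionally to zero when the SNP fixes; such
  replicates are redrawn since they contain no causal variant to recover).
* **Pyramiding**: five planted additive loci with effects large enough
  (0.75 liability units) that each usually exceeds the fixed genome-wide
  threshold, so the superior-allele count has support over several values.

## Numerical choices and degenerate inputs

Monomorphic SNPs: zero contribution to PCA/kinship, missing p in scans,
missing rows in r² matrices, errors when they are a region's lead.  Perfect
fits report p → 0 rather than failing.  Non-PSD kinship is shifted by its
smallest eigenvalue with a warning.  Negative NJ branch lengths clamp to 0.
Constant traits report missing skewness/kurtosis; constant phenotypes abort
permutation thresholds.  MAF boundary: a SNP at exactly 5% MAF or exactly 30%
missingness survives QC (the removal rules are strict inequalities).  CV is
reported as a fraction (0.37-style), the convention of the descriptive tables
this format mirrors.  All randomness flows through explicit integer seeds;
reruns are byte-identical.

## Known limitations

Single-trait scans only; no dominance or epistasis beyond the two-gene
cross-classification; no imputation; permutations run under the GLM only;
Tajima's D significance uses fixed configurable bounds rather than the exact
beta quantiles per n; the pipeline's haplotype stage needs external
functional annotation to distinguish nonsynonymous from promoter sites and
falls back to treating candidate-region members above the −log10 p cutoff as
the site set.
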