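"""Genome-wide significance thresholds: effective SNP count vs conditional
permutation.

The suggestive line is -log10(1/Neff) with Neff the LD-pruned marker count
(PLINK-style window 50 / step 50 / r2 >= 0.2).  The conditional permutation
splits the trait into a PC-fitted structure component P and residual G,
reshuffles only G, and takes the 5% quantile of genome-wide minimum p over
permuted scans — a structure-preserving Churchill-Doerge threshold.
"""

from saltgwas import (
    SimConfig, simulate_panel, filter_snps, compute_pca,
    ld_prune_neff, suggestive_threshold, conditional_permutation_threshold,
)

sim = simulate_panel(SimConfig(n_accessions=250, subpop_fractions=(0.6, 0.4),
                               n_chrom=4, snps_per_chrom=200, fst=0.25,
                               subpop_effect=0.8, seed=23))
panel = filter_snps(sim.genotypes)
pcs = compute_pca(panel, k=3)
y = sim.phenotypes["STL"].to_numpy(dtype=float)

neff = ld_prune_neff(panel)
print(f"LD pruning: {neff.neff} effective markers out of {panel.n_snps}")
print(f"suggestive threshold -log10(1/Neff) = {suggestive_threshold(neff):.3f}")

perm = conditional_permutation_threshold(panel, y, pcs, n_perm=300, alpha=0.05, seed=1)
print(f"conditional permutation threshold (5% family-wise) = {perm.threshold:.3f}")
# the permutation threshold is stricter than the suggestive line because it
# controls the genome-wide minimum p rather than a per-marker rate; both are
# fed to QTL clumping (a fixed threshold of 4.0 is also supported).
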