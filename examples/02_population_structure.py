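"""Quality control and population structure: PCA, kinship, neighbor joining.

SNPs failing the study's QC (missing rate > 30% or MAF < 5%) are removed; the
remaining dosages feed PCA (scan covariates), a VanRaden kinship matrix (the
mixed model's random effect) and an allele-sharing NJ tree.
"""

import numpy as np

from saltgwas import SimConfig, simulate_panel, filter_snps, compute_pca, compute_kinship
from saltgwas.structure import neighbor_joining, deepest_bipartition

sim = simulate_panel(SimConfig(n_accessions=200, subpop_fractions=(0.5, 0.5),
                               n_chrom=3, snps_per_chrom=150, fst=0.3, seed=11))
panel = filter_snps(sim.genotypes)
print(f"QC kept {panel.n_snps}/{sim.genotypes.n_snps} SNPs")

pcs = compute_pca(panel, k=3)
print(f"variance explained by PC1-3: "
      f"{', '.join(f'{v:.1%}' for v in pcs.variance_explained)}")
labels = np.array(sim.truth["subpop"])
side = pcs.scores[:, 0] > 0
agree = max((labels[side] == "indica").mean(), (labels[side] == "japonica").mean())
print(f"PC1 sign separates the two subpopulations with {agree:.0%} purity")

K = compute_kinship(panel)
print(f"kinship: diagonal mean {np.diag(K).mean():.2f}, "
      f"off-diagonal mean {K[~np.eye(len(K), dtype=bool)].mean():.3f}")
# within-subpopulation relatedness >> between: the GRM sees the same split

tree = neighbor_joining(panel, max_snps=300)
a, b = deepest_bipartition(tree)
lab = dict(zip(panel.accession_ids, labels))
match = max(sum(lab[x] == "indica" for x in a), sum(lab[x] == "japonica" for x in a))
print(f"NJ deepest split: {len(a)} vs {len(b)} accessions "
      f"({match}/{len(a)} on one side share a subpopulation label)")
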