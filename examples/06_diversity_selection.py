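"""Nucleotide diversity and Tajima's D, and the selection-classification rules.

A candidate gene that lost diversity in one population relative to a
reference (pi_ref/pi_focal > 2) with negative D is called under positive
selection; a diversity gain with large positive D suggests balancing
selection.  The first part shows a neutral simulated region classifying as
"none"; the second constructs a swept alignment (one dominant sequence plus
singleton mutations) whose signature triggers the positive-selection call.
"""

import numpy as np

from saltgwas import SimConfig, simulate_panel, tajimas_d, classify_selection
from saltgwas.panel_io import GenotypePanel
import pandas as pd

# --- neutral case: both subpopulations of a simulated panel ---------------
sim = simulate_panel(SimConfig(n_accessions=200, subpop_fractions=(0.5, 0.5),
                               n_chrom=2, snps_per_chrom=150, fst=0.2,
                               missing_rate=0.0, seed=37))
panel = sim.genotypes
labels = np.array(sim.truth["subpop"])
region = panel.snp_indices_in("chr01", 1, 30_000_000)[:80]

stats = {}
for pop in ("indica", "japonica"):
    sub = panel.subset(accessions=np.flatnonzero(labels == pop))
    stats[pop] = tajimas_d(sub, region, population=pop, region_id="gene1")
    st = stats[pop]
    print(f"{pop:10s} n={st.n:3d}  S={st.S:3d}  pi={st.pi_per_site:.4f}  "
          f"theta_W={st.theta_w_per_site:.4f}  D={st.tajima_d:+.2f}")
call = classify_selection(stats["japonica"], stats["indica"])
print(f"neutral region classification: {call.call} (pi ratio {call.pi_ratio:.2f})\n")


def _alignment_panel(h):
    """0/1 haploid alignment -> homozygous-coded GenotypePanel."""
    h = np.asarray(h, dtype=np.int8)
    n, m = h.shape
    snps = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, m + 1) * 100,
                         "id": [f"s{j}" for j in range(m)], "ref": "A", "alt": "G"})
    return GenotypePanel([f"acc{i}" for i in range(n)], snps, h * 2)


# --- swept case: 40 near-identical sequences with singleton mutations ------
rng = np.random.default_rng(0)
L, n = 120, 40
swept = np.zeros((n, L), dtype=int)
for k in range(12):  # recent mutations, each on a single sequence
    swept[rng.integers(n), rng.integers(L)] = 1
diverse = rng.integers(0, 2, size=(n, L))  # reference population, high diversity

focal = tajimas_d(_alignment_panel(swept), range(L), population="indica", region_id="gene2")
ref = tajimas_d(_alignment_panel(diverse), range(L), population="wild", region_id="gene2")
print(f"swept:    pi={focal.pi_per_site:.4f}  D={focal.tajima_d:+.2f}")
print(f"diverse:  pi={ref.pi_per_site:.4f}  D={ref.tajima_d:+.2f}")
call = classify_selection(focal, ref)
print(f"classification ({call.comparison}): {call.call}"
      f"  [pi ratio {call.pi_ratio:.1f}, D {call.tajima_d:+.2f}]")
# the diversity collapse (ratio >> 2) together with the singleton excess
# (D < 0) is the footprint the positive-selection rule looks for.
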