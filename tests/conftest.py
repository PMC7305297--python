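import numpy as np
import pandas as pd
import pytest

from saltgwas.panel_io import SNP_COLUMNS, GenotypePanel


def make_panel(dosages, positions=None, chrom="chr01", ref="A", alt="G", accession_ids=None):
    """Build a GenotypePanel from a raw dosage array (rows = accessions)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if accession_ids is None:
        accession_ids = [f"ACC{i:03d}" for i in range(n)]
    if isinstance(chrom, str):
        chroms = [chrom] * m
    else:
        chroms = list(chrom)
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
            "ref": ref,
            "alt": alt,
        },
        columns=SNP_COLUMNS,
    )
    return GenotypePanel(accession_ids=accession_ids, snps=snps, dosages=d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def structured_sim():
    """A two-subpopulation panel at fst=0.3 shared across structure tests."""
    from saltgwas.syndata import SimConfig, simulate_panel

    cfg = SimConfig(
        n_accessions=200, subpop_fractions=(0.5, 0.5), n_chrom=3,
        snps_per_chrom=120, fst=0.3, missing_rate=0.02, seed=11,
    )
    return simulate_panel(cfg)
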