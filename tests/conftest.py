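import numpy as np
import pandas as pd
import pytest

from alkagerm.io_formats import VariantTable
from alkagerm.synthetic_data import CausalGene, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic panel with one planted 1.2-SD causal gene."""
    cfg = SimConfig(
        n_accessions=250, n_snps=6000, n_chromosomes=6, n_genes=20,
        causal_genes=[CausalGene(0, 0, 1.2)], seed=5,
    )
    return simulate_dataset(cfg)


def make_variant_table(dosages, chrom="1", start_pos0=100, spacing=1000,
                       ref="A", alt="G", samples=None):
    """VariantTable from a (n_snps, n_samples) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    samples = samples or [f"S{i + 1:03d}" for i in range(n)]
    pos0 = start_pos0 + spacing * np.arange(m)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{chrom}_{p + 1}" for p in pos0],
            "chrom": chrom,
            "pos0": pos0,
            "ref": ref,
            "alt": alt,
        }
    )
    return VariantTable(snps, dosages, samples)


@pytest.fixture(scope="session")
def variant_table_factory():
    return make_variant_table
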