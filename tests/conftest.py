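import numpy as np
import pandas as pd
import pytest

from tmgate.io import SampleBundle
from tmgate.simulate import SimConfig, simulate_paired_sample


def make_bundle(counts, genes=None, barcodes=None, species="human", **meta_cols):
    """Small helper: bundle from a dense genes x cells array."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_cells = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for k, v in meta_cols.items():
        meta[k] = v
    return SampleBundle(sample_id="test", species=species, counts=counts,
                        gene_ids=np.array(genes, dtype=object), cell_meta=meta)


@pytest.fixture(scope="session")
def sim_sample():
    """One mid-sized simulated paired sample shared across tests."""
    return simulate_paired_sample(SimConfig(rng_seed=11, n_blood=1200, n_tumor=900,
                                            n_genes=120))


@pytest.fixture(scope="session")
def sim_small():
    return simulate_paired_sample(SimConfig(rng_seed=5, n_blood=400, n_tumor=300,
                                            n_genes=60))
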