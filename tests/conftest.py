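import numpy as np
import pandas as pd
import pytest

import cd4atlas as ca

ATLAS_SEED = 11


@pytest.fixture(scope="session")
def atlas():
    """Default-condition atlas: 6 subtypes x 2 replicates, 2000 genes,
    50 planted SU genes/subtype at +3 log2, 30 planted switches."""
    return ca.evaluation.run_atlas(ATLAS_SEED)


@pytest.fixture(scope="session")
def small_atlas():
    config = ca.SimConfig(
        n_genes=300, su_per_subtype=5, n_switch_genes=8, reads_per_gene=200, seed=5
    )
    counts, samples, genes, catalog, compat, truth = ca.generate_all(config)
    return {
        "config": config,
        "counts": counts,
        "samples": samples,
        "genes": genes,
        "catalog": catalog,
        "compat": compat,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def atlas_psi(atlas):
    return ca.estimate_psi_table(atlas["compat"], atlas["catalog"], atlas["samples"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_counts(array, genes=None, samples=None) -> pd.DataFrame:
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return pd.DataFrame(array, index=genes, columns=samples)
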