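import numpy as np
import pandas as pd
import pytest

import drivernet as dn


def make_expr(values, genes=None, samples=None, groups=None, log2=True):
    """Small helper to build an ExpressionMatrix from a 2D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    grp = pd.Series(groups, index=samples) if groups is not None else pd.Series(dtype=object)
    return dn.ExpressionMatrix(values=df, groups=grp, log2_transformed=log2)


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulation shared across tests."""
    cfg = dn.SimConfig(seed=7)
    a, b, hmap, truth = dn.generate_paired_datasets(cfg)
    return cfg, a, b, hmap, truth


@pytest.fixture(scope="session")
def sim_modules_only():
    """Three planted modules, no differential expression."""
    cfg = dn.SimConfig(
        n_genes_per_species=300,
        n_shared_homologs=200,
        module_sizes=(40, 40, 40),
        shared_module_fraction=1.0,
        n_de_genes=0,
        seed=3,
    )
    a, b, hmap, truth = dn.generate_paired_datasets(cfg)
    return cfg, a, b, hmap, truth
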