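import numpy as np
import pandas as pd
import pytest

from crossblup import (
    PopulationSpec,
    WorkingSet,
    align_datasets,
    deregress,
    impute_missing,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_data():
    """A small but fully structured two-line + F1 dataset."""
    spec = PopulationSpec(
        n_per_line=200, n_f1=100, n_snps=1000, n_qtl=150,
        n_base_per_line=60, effective_size=60, drift_generations=15,
        f1_n_sires=25, f1_n_dams=50, seed=42,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def small_working_set(small_data):
    """QC'd, imputed, deregressed working set over the small dataset."""
    g = impute_missing(small_data.genotypes, mode="mean", seed=0)
    res = deregress(small_data.traits, ped=small_data.pedigree,
                    h2=small_data.spec.h2, mode="parent_adjusted")
    g2, tr2, _ = align_datasets(g, small_data.pedigree, res.table)
    return WorkingSet(genotypes=g2, pedigree=small_data.pedigree, traits=tr2)


@pytest.fixture()
def tiny_pedigree_df():
    return pd.DataFrame({
        "animal": ["S", "D", "A", "B", "C"],
        "sire":   ["0", "0", "S", "S", "A"],
        "dam":    ["0", "0", "D", "D", "B"],
        "line":   ["L1"] * 5,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
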