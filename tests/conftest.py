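import numpy as np
import pandas as pd
import pytest

from cytoscreen import (
    ClinicalTable,
    ExpressionMatrix,
    PlantedGene,
    PlantedPair,
    SyntheticCohortConfig,
    simulate_cohort,
    zscore_normalize,
)


@pytest.fixture(scope="session")
def null_cohort():
    """208-patient cohort with no planted effects."""
    return simulate_cohort(SyntheticCohortConfig(n_samples=208, n_genes=50, rng_seed=101))


@pytest.fixture(scope="session")
def planted_cohort():
    """One harmful gene (beta = 1.2) among nulls."""
    cfg = SyntheticCohortConfig(
        n_samples=200, n_genes=50,
        planted_single_genes=(PlantedGene("PLANTED", 1.2),),
        rng_seed=202,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pair_cohort():
    """One correlated ligand-receptor pair with a shared hazard effect."""
    cfg = SyntheticCohortConfig(
        n_samples=208, n_genes=40,
        planted_pairs=(PlantedPair("LIG_TRUE", "REC_TRUE", rho=0.77, beta=0.9),),
        rng_seed=303,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def normalized_null(null_cohort):
    return zscore_normalize(null_cohort.expression)


@pytest.fixture(scope="session")
def normalized_pair(pair_cohort):
    return zscore_normalize(pair_cohort.expression)


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples with one missing value."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.5, np.nan, 1.5, 2.5]],
        index=pd.Index(["GA", "GB", "GC"], name="gene"),
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(values=df)


@pytest.fixture()
def tiny_clinical():
    return ClinicalTable(
        data=pd.DataFrame(
            {
                "os_months": [10.0, 5.0, 20.0, 2.0],
                "os_event": [1.0, 1.0, 0.0, 1.0],
                "dfs_months": [8.0, 4.0, 15.0, 1.0],
                "dfs_event": [1.0, 0.0, 0.0, 1.0],
            },
            index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        )
    )
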