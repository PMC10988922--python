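import pandas as pd
import pytest

import insituanno as ia


@pytest.fixture
def tiny_matrix() -> ia.GeneExpressionMatrix:
    """3 genes x 2 cells of raw counts with known values."""
    values = pd.DataFrame(
        [[1, 4], [1, 0], [2, 6]], index=["g1", "g2", "g3"], columns=["c1", "c2"]
    )
    return ia.GeneExpressionMatrix(values, layer="raw")


@pytest.fixture(scope="session")
def small_dataset() -> ia.SyntheticDataset:
    """Down-scaled simulated experiment for fast unit tests."""
    return ia.simulate_dataset(
        n_genes=400, markers_per_type=10, cells_per_type=60, seed=11
    )


@pytest.fixture(scope="session")
def study_dataset() -> ia.SyntheticDataset:
    """Full study-design simulation: 3 types, 3 LCM replicates, 2000 genes,
    20 markers/type at log2 fold 3, 300 cells/type."""
    return ia.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def study_analysis(study_dataset):
    """Similarity table + fitted concordance on the study-design dataset."""
    sim, est = ia.analyze(
        study_dataset.cells,
        study_dataset.references,
        study_dataset.truth.marker_catalog(),
    )
    return sim, est
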