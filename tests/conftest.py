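import numpy as np
import pandas as pd
import pytest

from hippoaxis.datamodel import ExpressionMatrix, SampleMetadata, aggregate_replicates
from hippoaxis.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default stated-world synthetic dataset (calibrated replicate noise)."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noiseless limit: replicate_cv = 0, planted folds exact."""
    return generate_dataset(SimConfig(seed=1, replicate_cv=0.0))


@pytest.fixture(scope="session")
def noiseless_pm(noiseless_sim):
    matrix, meta, manifest = noiseless_sim
    return aggregate_replicates(matrix.drop_genes(manifest.spike_in_genes), meta)


@pytest.fixture(scope="session")
def default_pm(default_sim):
    matrix, meta, manifest = default_sim
    return aggregate_replicates(matrix.drop_genes(manifest.spike_in_genes), meta)


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[10.0, 12.0, 0.0, 1.0], [5.0, 6.0, 100.0, 90.0], [0.0, 0.0, 2.0, 3.0]],
        index=["g1", "g2", "g3"],
        columns=["A_r1", "A_r2", "B_r1", "B_r2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def tiny_meta():
    return SampleMetadata(
        pd.DataFrame(
            {
                "cell_class": ["CA1", "CA1", "CA3", "CA3"],
                "region": ["dorsal", "dorsal", "ventral", "ventral"],
                "replicate": [1, 2, 1, 2],
            },
            index=pd.Index(["A_r1", "A_r2", "B_r1", "B_r2"], name="sample_id"),
        )
    )
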