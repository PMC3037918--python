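import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rankscreen as rs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_cohort() -> pd.DataFrame:
    return rs.reference_tma_cohort()


@pytest.fixture
def toy_dataset() -> rs.ExpressionDataset:
    """3 genes x (2 disease + 2 normal) samples, hand-checkable."""
    matrix = pd.DataFrame(
        {
            "d1": [5.0, 1.0, 3.0],
            "d2": [4.0, 2.0, 3.0],
            "n1": [1.0, 5.0, 3.0],
            "n2": [2.0, 4.0, 3.0],
        },
        index=["gA", "gB", "gC"],
    )
    annotations = pd.DataFrame(
        {
            "disease_concept": "dz",
            "state": ["disease", "disease", "normal", "normal"],
            "tissue": "t",
        },
        index=pd.Index(["d1", "d2", "n1", "n2"], name="sample_id"),
    )
    return rs.ExpressionDataset("toy", matrix, annotations)


def make_dataset(rng: np.random.Generator, n_genes: int, n_dz: int, n_nm: int,
                 disease: str = "dz", dataset_id: str = "ds") -> rs.ExpressionDataset:
    """Random dataset helper for property tests."""
    samples = [f"{dataset_id}_d{i}" for i in range(n_dz)] + [
        f"{dataset_id}_n{i}" for i in range(n_nm)
    ]
    matrix = pd.DataFrame(
        rng.normal(size=(n_genes, n_dz + n_nm)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    annotations = pd.DataFrame(
        {
            "disease_concept": disease,
            "state": ["disease"] * n_dz + ["normal"] * n_nm,
            "tissue": "t",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return rs.ExpressionDataset(dataset_id, matrix, annotations)
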