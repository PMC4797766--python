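import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from refstab import CqMatrix, default_truth, generate_cq_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def small_matrix() -> CqMatrix:
    """3 samples x 3 genes with hand-checkable pairwise SDs."""
    return CqMatrix(pd.DataFrame(
        {"A": [20.0, 21.0, 20.5],
         "B": [25.0, 26.0, 25.5],
         "C": [30.0, 31.0, 30.4]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id")))


@pytest.fixture
def random_matrix() -> CqMatrix:
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        rng.uniform(20.0, 32.0, size=(12, 6)),
        index=[f"s{i}" for i in range(12)],
        columns=[f"g{j}" for j in range(6)])
    return CqMatrix(vals)


@pytest.fixture(scope="session")
def beluga_like_dataset():
    """Default synthetic study: 13 genes x 60 samples, triplicates."""
    truth = default_truth(seed=11)
    return generate_cq_dataset(truth, n_samples=60)
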