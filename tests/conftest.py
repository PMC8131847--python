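import numpy as np
import pandas as pd
import pytest

from diffcoexpr.data_io import ExpressionMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 16 samples of independent noise."""
    values = rng.standard_normal((10, 16))
    genes = [f"G{i:02d}" for i in range(10)]
    samples = [f"S{j:02d}" for j in range(16)]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def two_condition_pheno(small_matrix):
    """8 normal + 8 tumor samples matching small_matrix."""
    condition = ["normal"] * 8 + ["tumor"] * 8
    return PhenotypeTable(pd.DataFrame({"condition": condition}, index=small_matrix.sample_ids))


@pytest.fixture
def survival_pheno(rng):
    """30 tumor samples with exponential survival, ~20% censored."""
    n = 30
    times = rng.exponential(10.0, n)
    event = (times <= 15.0).astype(float)
    times = np.minimum(times, 15.0)
    return PhenotypeTable(
        pd.DataFrame(
            {"condition": ["tumor"] * n, "survival_time": times, "event": event},
            index=[f"T{i:02d}" for i in range(n)],
        )
    )
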