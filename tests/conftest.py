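import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from latentpop import GenotypeMatrix, build_design

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genotypes():
    """4 diploid individuals, 2 biallelic loci: two clear genetic groups."""
    codes = np.array(
        [
            [[0, 0], [0, 0]],
            [[0, 0], [0, 1]],
            [[1, 1], [1, 0]],
            [[1, 1], [1, 1]],
        ]
    )
    return GenotypeMatrix(
        codes=codes,
        missing_mask=np.zeros_like(codes, dtype=bool),
        n_alleles=np.array([2, 2]),
        individual_ids=["a", "b", "c", "d"],
    )


@pytest.fixture
def intercept_design(toy_genotypes):
    table = pd.DataFrame({"id": toy_genotypes.individual_ids})
    return build_design(table, geo_trend="none")


@pytest.fixture
def geo_table():
    r = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "id": [f"i{i}" for i in range(12)],
            "latitude": r.uniform(-1, 1, 12),
            "longitude": r.uniform(-1, 1, 12),
            "language": list("AAABBBCCCDDD"),
        }
    )
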