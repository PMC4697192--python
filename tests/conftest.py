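import numpy as np
import pandas as pd
import pytest

from cyp19mr import GenotypeMatrix, SimulationConfig, VariantRecord


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=11,
        n_variants=6,
        study_sizes=((400, 2000), (300, 1200)),
        adjacent_r2=0.6,
    )


@pytest.fixture
def toy_genotypes():
    """Six samples, two variants, hand-set dosages."""
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(1, 7)],
        variants=[
            VariantRecord(id="v1", position=100),
            VariantRecord(id="v2", position=200),
        ],
        dosage=np.array([[0, 0], [1, 0], [2, 1], [0, 1], [1, 2], [2, 2]], float),
    )


def make_pheno(n, status=None, rng=None, **extra):
    rng = rng or np.random.default_rng(0)
    base = {
        "sample_id": [f"s{i}" for i in range(1, n + 1)],
        "status": status if status is not None else rng.integers(0, 2, n),
    }
    base.update(extra)
    return pd.DataFrame(base)
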