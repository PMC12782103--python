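import numpy as np
import pandas as pd
import pytest

from panomix.data import MetadataTable, OmicsMatrix, ResponseSpec, Study
from panomix.simulate import SimSpec, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """40 samples, two gaussian modalities, strong planted signal."""
    study, truth = simulate_study(
        SimSpec(n=40, p=(30, 25), q=(3, 3), delta=2.0, seed=11)
    )
    return study, truth


@pytest.fixture(scope="session")
def count_study():
    """Negative-binomial count study for the precision-weight path."""
    study, truth = simulate_study(
        SimSpec(n=16, p=(500,), q=(25,), delta=2.0, noise="negative_binomial", seed=5)
    )
    return study, truth


@pytest.fixture()
def tiny_study():
    """Hand-built 8-sample study with one predictive feature."""
    rng = np.random.default_rng(0)
    meta = pd.DataFrame(
        {
            "group": ["a", "a", "a", "a", "b", "b", "b", "b"],
            "age": [31.0, 45.0, 52.0, 28.0, 60.0, 41.0, 39.0, 55.0],
        }
    )
    metadata = MetadataTable(meta, {"group": "categorical", "age": "numerical"})
    response = ResponseSpec("group", "a", ("a", "b"))
    X = rng.standard_normal((8, 6))
    X[:, 0] += np.where(meta["group"] == "b", 2.0, 0.0)
    ds = OmicsMatrix("omics", pd.DataFrame(X, columns=[f"F{i}" for i in range(6)]), False)
    return Study(metadata, [ds], response)
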