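import numpy as np
import pandas as pd
import pytest

from comorbidnet import expression, synthdata


@pytest.fixture(scope="session")
def default_bundles():
    """Default two-tissue expression scenario, seed 1."""
    return synthdata.gen_expression(synthdata.ExprScenario(seed=1))


@pytest.fixture(scope="session")
def adjusted_bundles(default_bundles):
    return [expression.batch_adjust(b) for b in default_bundles]


@pytest.fixture(scope="session")
def small_bundle():
    """Tiny handmade bundle for exact-value tests."""
    rng = np.random.default_rng(42)
    matrix = pd.DataFrame(rng.normal(5, 1, size=(20, 12)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(12)])
    samples = pd.DataFrame({
        "sample": matrix.columns,
        "tissue": "tissue1",
        "batch": ["B1"] * 6 + ["B2"] * 6,
        "group": (["disease"] * 3 + ["control"] * 3) * 2,
        "subtype": "NA",
        "disease_activity": rng.normal(size=12),
        "crp": rng.uniform(1, 5, size=12),
    })
    return synthdata.ExpressionBundle(matrix=matrix, samples=samples)
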