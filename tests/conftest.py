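import numpy as np
import pandas as pd
import pytest

import modscape as msc


@pytest.fixture(scope="session")
def mini_data():
    """The small planted scenario: 400 genes, 30 samples, 3 modules, 2 datasets."""
    return msc.generate(msc.standard_scenarios()["mini"])


@pytest.fixture(scope="session")
def mini_modules(mini_data):
    """Module set built from the planted truth of the mini scenario."""
    from modscape.benchmark import _truth_moduleset
    return _truth_moduleset(mini_data.expr, mini_data.truth.assignments)


@pytest.fixture(scope="session")
def recovery_detection():
    """One full detect_modules run on the recovery preset (shared; ~3 s)."""
    data = msc.generate(msc.standard_scenarios()["recovery"])
    ms = msc.detect_modules(data.expr, power=6, mode="signed_hybrid")
    return data, ms


@pytest.fixture()
def small_expr():
    """Deterministic 6-gene x 8-sample dataset with two correlated pairs."""
    rng = np.random.default_rng(123)
    f = rng.standard_normal(8)
    x = np.vstack([
        f + 0.1 * rng.standard_normal(8),
        f + 0.1 * rng.standard_normal(8),
        -f + 0.1 * rng.standard_normal(8),
        rng.standard_normal(8),
        rng.standard_normal(8),
        rng.standard_normal(8),
    ])
    return msc.ExpressionDataset(x + 8, [f"g{i}" for i in range(6)], [f"s{j}" for j in range(8)])


@pytest.fixture()
def simple_design():
    table = pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(8)],
        "tissue": ["blood"] * 4 + ["epidermis"] * 4,
        "condition": (["syn", "allo"] * 4),
        "replicate": [1, 1, 2, 2] * 2,
    }).set_index("sample_id")
    return msc.TraitDesign(table)
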