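import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from xgbcda import (
    AssociationMatrix,
    BoosterParams,
    ExpressionProfileSet,
    SimilarityMatrix,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Desk-size synthetic dataset: 40 circRNAs x 16 diseases, 12 samples."""
    return generate_dataset(
        SyntheticConfig(n_circ=40, n_dis=16, n_samples=12, n_circ_groups=4, n_dis_groups=4, seed=7)
    )


@pytest.fixture(scope="session")
def small_params():
    """Reduced booster for fast unit tests; tuned defaults are exercised elsewhere."""
    return BoosterParams(n_estimators=40)


@pytest.fixture
def toy_assoc():
    return AssociationMatrix(
        ["c1", "c2", "c3"],
        ["d1", "d2"],
        np.array([[1, 0], [0, 1], [1, 1]]),
    )


@pytest.fixture
def toy_expr():
    return ExpressionProfileSet(
        ["c1", "c2", "c3"],
        ["s1", "s2", "s3"],
        np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 1.0, 1.0]]),
    )


@pytest.fixture
def toy_dsim():
    return SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
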