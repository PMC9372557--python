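import numpy as np
import pytest

from dietmcda.ahp import PairwiseComparisonMatrix, WeightVector
from dietmcda.evidence import Criterion, DecisionMatrix, ValueSemantics


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def simple_weights():
    return WeightVector(["c1", "c2", "c3"], [0.5, 0.3, 0.2])


@pytest.fixture
def cyclic_pcm():
    """Maximally inconsistent 3x3 judgment cycle (c1>c2>c3>c1)."""
    return PairwiseComparisonMatrix(
        ["c1", "c2", "c3"],
        [[1, 3, 1 / 3], [1 / 3, 1, 3], [3, 1 / 3, 1]],
    )


def make_matrix(values, semantics=ValueSemantics.PERCENT_REDUCTION, objective="minimize"):
    """Small decision matrix with generic minimized criteria."""
    values = np.asarray(values, dtype=float)
    n_alt, n_crit = values.shape
    criteria = [
        Criterion(f"C{j + 1}", f"criterion {j + 1}", "environment", objective, "%")
        for j in range(n_crit)
    ]
    return DecisionMatrix(
        alternatives=[f"alt_{i + 1}" for i in range(n_alt)],
        criteria=criteria,
        values=values,
        semantics=semantics,
    )
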