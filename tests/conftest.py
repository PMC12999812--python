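import numpy as np
import pandas as pd
import pytest

from coexnet.containers import CountMatrix, ExpressionMatrix, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    values = rng.integers(0, 200, size=(20, 5))
    return CountMatrix.from_arrays(
        values, [f"G{i}" for i in range(20)], [f"S{j}" for j in range(5)]
    )


@pytest.fixture
def small_expr(rng) -> ExpressionMatrix:
    values = rng.normal(8.0, 1.0, size=(12, 10))
    return ExpressionMatrix.from_arrays(
        values, [f"G{i}" for i in range(12)], [f"S{j}" for j in range(10)]
    )


@pytest.fixture
def binary_samples() -> SampleTable:
    ids = [f"S{j}" for j in range(10)]
    return SampleTable(pd.DataFrame({"trait": [1] * 6 + [0] * 4}, index=ids))


def make_expression(values, prefix_g="G", prefix_s="S") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix.from_arrays(
        values,
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{j}" for j in range(values.shape[1])],
    )
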