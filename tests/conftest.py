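import numpy as np
import pytest

from rosie.io_prep import ClassLabels, ExpressionMatrix


def make_matrix(values, sample_prefix="S", feature_prefix="F", log_scale=False):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        np.array([f"{sample_prefix}{i:03d}" for i in range(n)], dtype=object),
        np.array([f"{feature_prefix}{j:03d}" for j in range(p)], dtype=object),
        log_scale=log_scale,
    )


@pytest.fixture
def two_class_separable():
    """n=40, p=10: classes differ strongly only in feature 0."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 10))
    y = np.repeat([0, 1], 20)
    X[y == 1, 0] += 8.0
    return make_matrix(X), ClassLabels(y)


@pytest.fixture(scope="session")
def simulation_study_table():
    """Ten-seed simulation study at reduced dimensionality (p=800).

    Shared session-wide: the qualitative ranking properties of the three
    scenarios are checked against this one table.
    """
    from rosie.simulate import run_simulation_study

    return run_simulation_study(seeds=tuple(range(1, 11)), n=200, p=800)
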