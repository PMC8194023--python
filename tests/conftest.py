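import numpy as np
import pytest

from lonnrec import encode_and_normalize, generate_fixture_cohort


@pytest.fixture(scope="session")
def cohort299():
    """Reference fixture cohort used across modules (n=299, fixed seed)."""
    return generate_fixture_cohort(299, seed=20240101)


@pytest.fixture(scope="session")
def encoded299(cohort299):
    X, Y, spec = encode_and_normalize(cohort299)
    return X, Y, spec


class StubModel:
    """Duck-typed model returning fixed predictions (for pure-logic tests)."""

    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=float)

    def predict(self, X):
        X = np.asarray(X)
        n = 1 if X.ndim == 1 else X.shape[0]
        return np.tile(self.outputs, (n, 1))


@pytest.fixture
def stub_model_factory():
    return StubModel
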