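import numpy as np
import pytest

from avifuse import ModelPrediction, build_default_fis


@pytest.fixture(scope="session")
def fis3():
    """Default 3-model fuzzy inference system (session-scoped: it is immutable)."""
    return build_default_fis(3)


def make_row(prob_rows):
    """Build a panel row (list of ModelPrediction) from raw probability rows."""
    return [ModelPrediction.from_probs(f"m{i + 1}", np.asarray(p, float))
            for i, p in enumerate(prob_rows)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
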