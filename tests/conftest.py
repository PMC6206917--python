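import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dkbcgs import ExpressionDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """4 samples x 3 genes, two classes, hand-written values."""
    values = np.array(
        [
            [1.0, 2.0, 0.0],
            [3.0, 4.0, 0.0],
            [0.0, 6.0, 1.0],
            [2.0, 8.0, 3.0],
        ]
    )
    return ExpressionDataset(
        values,
        ["s1", "s2", "s3", "s4"],
        ["gA", "gB", "gC"],
        np.array(["tumor", "tumor", "normal", "normal"]),
    )
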