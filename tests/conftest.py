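import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acb.io_formats import ExpressionMatrix, Layer, SensitivityVector, Units
from acb.synthetic_data import SyntheticConfig, generate_panel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel31():
    """Default study-condition panel: 31 samples, 2000 genes, 15 planted."""
    return generate_panel(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def panel200():
    """High-power panel for recovery checks."""
    return generate_panel(SyntheticConfig(n_samples=200, seed=1))


@pytest.fixture()
def tiny_matrix():
    frame = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.5], [2.0, 0.5, 1.5]],
        index=["s1", "s2", "s3", "s4"],
        columns=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(frame, Layer.expression, Units.log2tpm1)


@pytest.fixture()
def tiny_sensitivity():
    return SensitivityVector(
        pd.Series([0.5, 1.0, 4.0, 2.0], index=["s1", "s2", "s3", "s4"]), metric="ec50"
    )


def fisher_z_interval(r: float, n: int, z_crit: float = 1.96) -> tuple[float, float]:
    """95% sampling interval for a sample correlation at true r and size n."""
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - z_crit * se)), float(np.tanh(z + z_crit * se))
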