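import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cdaa.synthetic import CascadeSpec, generate_cascade

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TIMES = [0.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0]


@pytest.fixture
def small_expr():
    """Five genes on the canonical uneven grid: one early mover, a late wave."""
    values = np.array(
        [
            [0.0, 1.0, 2.0, 4.0, 4.1, 4.0, 4.0],
            [0.0, 0.1, 0.0, 0.1, 3.0, 3.1, 3.0],
            [1.0, 1.1, 1.0, 0.9, -2.0, -2.1, -2.0],
            [0.5, 0.4, 0.5, 0.6, 3.6, 3.5, 3.6],
            [0.0, 0.0, 0.1, 0.0, 2.4, 2.5, 2.4],
        ]
    )
    genes = ["early", "late1", "late2", "late3", "late4"]
    return pd.DataFrame(values, index=genes, columns=TIMES)


@pytest.fixture(scope="session")
def default_cascade():
    spec = CascadeSpec()
    expr, truth = generate_cascade(spec)
    return spec, expr, truth


@pytest.fixture(scope="session")
def clean_cascade():
    spec = CascadeSpec(noise_sd=0.0)
    expr, truth = generate_cascade(spec)
    return spec, expr, truth
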