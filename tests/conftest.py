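import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sinustd as st

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def standard_outline():
    """One deterministic eligible synthetic outline with its baseline and origin."""
    return st.generate_outline(seed=42)


@pytest.fixture(scope="session")
def standard_profile(standard_outline):
    outline, baseline, origin = standard_outline
    return st.measure_profile(outline, baseline, origin)


def semicircle_arc(radius: float = 20.0, n: int = 721) -> st.SinusOutline:
    """Semicircular arc centred on the coordinate origin, left to right terminus."""
    t = np.linspace(np.pi, 0.0, n)
    return st.SinusOutline.from_coords(
        np.column_stack([radius * np.cos(t), radius * np.sin(t)]), id="semicircle")
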