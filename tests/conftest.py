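import numpy as np
import pytest

from ccopheno.synth import (
    CalciumSimParams,
    OrganoidSimParams,
    make_calcium_trace,
    make_organoid_video,
)


@pytest.fixture(scope="session")
def default_video():
    """One default synthetic beating-organoid recording with its truth."""
    return make_organoid_video(OrganoidSimParams(seed=7))


@pytest.fixture(scope="session")
def default_area_trace(default_video):
    from ccopheno.segment import segment_stack

    stack, _ = default_video
    return segment_stack(stack)


@pytest.fixture(scope="session")
def default_calcium():
    """One default synthetic calcium recording with its truth."""
    return make_calcium_trace(CalciumSimParams(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
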