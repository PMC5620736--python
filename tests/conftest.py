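from datetime import datetime

import pytest

from bms import TimeGrid, build_model, default_layout, generate, profile_a


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def grid():
    return TimeGrid(delta_t=60)


@pytest.fixture(scope="session")
def stream_a(layout):
    """Five weeks of Profile A starting Monday 2024-01-01 (seed 7)."""
    return generate(profile_a(), layout, start=datetime(2024, 1, 1), weeks=5, seed=7)


@pytest.fixture(scope="session")
def model_a(stream_a, layout):
    """Four-week model learned from the first four weeks of Profile A."""
    return build_model(stream_a, layout, window_start=datetime(2024, 1, 1), window_weeks=4)
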