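import numpy as np
import pytest

from aerovol import ScenarioConfig


@pytest.fixture
def default_config():
    """The standard acquisition scenario (full protocol, noise on)."""
    return ScenarioConfig(rng_seed=0)


@pytest.fixture
def validation_config():
    """Noiseless weak-phase imaging scenario.

    Reduced index contrast keeps droplets of a few um^3 within the
    weak-phase regime (peak delay below pi/2) while spanning several
    pixels, so forward/inverse checks probe the optics rather than the
    sampling limit.
    """
    return ScenarioConfig(
        delta_n=0.1,
        shot_noise=False,
        read_noise_counts=0.0,
        rng_seed=0,
    )


@pytest.fixture
def stats_config():
    """Large-substrate scenario for study-level statistics.

    The wide field mirrors the real sensor's multi-millimetre field of
    view and lets many particles coexist; these studies are never
    rendered, only their ground truth is used.
    """
    return ScenarioConfig(
        field_width_px=1024,
        field_height_px=1024,
        rng_seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
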