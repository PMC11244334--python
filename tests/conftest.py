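import numpy as np
import pytest

from adipotrace.simulate import ChannelIntensity, SimulationConfig


def noiseless_intensity(gfp_pos=200, gfp_neg=150, rfp_pos=150, rfp_neg=6000,
                        marker=20000, nuclear=8000, background=100):
    """Channel model with zero cell-to-cell variability (exactness tests)."""
    return {
        "nuclear": ChannelIntensity(background, nuclear, nuclear, 0.0),
        "gfp": ChannelIntensity(background, gfp_pos, gfp_neg, 0.0),
        "rfp": ChannelIntensity(background, rfp_pos, rfp_neg, 0.0),
        "marker": ChannelIntensity(background, marker, 0.0, 0.0),
    }


@pytest.fixture
def noiseless_config():
    """10 well-separated constant-intensity nuclei, no noise."""
    return SimulationConfig(
        n_cells=10,
        nucleus_radius_sd=0.0,
        min_center_distance=40.0,
        read_noise_sd=0.0,
        intensity=noiseless_intensity(),
        frac_gfp_pos=0.5,
        p_marker_pos_given_gfp_neg=0.5,
        seed=42,
    )


@pytest.fixture
def default_field():
    """A default-noise field with its ground truth."""
    from adipotrace.simulate import simulate_field

    return simulate_field(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240711)
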