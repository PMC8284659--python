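import numpy as np
import pytest

import cometkit as ck


@pytest.fixture
def clean_config():
    """Noiseless, lattice-free acquisition settings for exact fixtures."""
    return ck.SimConfig(axon_length_um=30.0, lattice_intensity=0.0,
                        bg_offset=50.0, poisson_noise=False,
                        gaussian_noise_sd=0.0)


@pytest.fixture
def straight_trace(clean_config):
    trace, curls = ck.simulate_axon_trace(clean_config)
    assert curls == []
    return trace


def make_comets(positions_um, amplitude=4000.0, tail_um=1.0, velocity=0.2):
    """Comets alive on [0, 10] s at the given arclength positions (at t=1 s
    each tip sits at position + velocity)."""
    return [ck.CometTrackTruth(0.0, 10.0, float(s) - velocity, velocity,
                               amplitude, tail_um)
            for s in positions_um]


@pytest.fixture
def snr5(request):
    """Scale Gaussian noise so comet peak / noise sd = 5 for a config."""
    def _apply(config):
        peak = ck.comet_peak_intensity(config)
        config.gaussian_noise_sd = peak / 5.0
        config.poisson_noise = False
        return config
    return _apply
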