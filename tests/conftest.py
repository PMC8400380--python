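import numpy as np
import pytest

from kspacesplice import (
    PhantomSpec,
    ReceiverModel,
    default_partition,
    simulate_study,
)

#: Receiver with noise and quantization disabled: the identity chain up to gain.
IDEAL_RX = ReceiverModel(pre_noise_sigma=0.0, post_noise_sigma=0.0, adc_bits=0)

#: Receiver whose used estimation lines sit far above the noise floor
#: (per-sample magnitude SNR >= 20 over the middle-N window of regions 2-3).
LOW_NOISE_RX = ReceiverModel(pre_noise_sigma=1.8e-5, post_noise_sigma=0.0, adc_bits=0)


@pytest.fixture(scope="session")
def partition220():
    return default_partition(220)


@pytest.fixture(scope="session")
def default_study():
    """The nominal three-gain study: 12-bit ADC, quantization-limited outer lines."""
    return simulate_study(seeds=(101, 202, 303))


@pytest.fixture(scope="session")
def noiseless_study():
    """Exact-ratio acquisitions: the no-noise fixed point of the splice."""
    return simulate_study(base_rx=IDEAL_RX, seeds=(1, 2, 3))


@pytest.fixture(scope="session")
def low_noise_study():
    """Noise present but far below every estimation sample."""
    return simulate_study(base_rx=LOW_NOISE_RX, seeds=(11, 22, 33))


@pytest.fixture(scope="session")
def phantom_image():
    from kspacesplice import make_phantom

    return make_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
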