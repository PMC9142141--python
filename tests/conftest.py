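import numpy as np
import pytest

from glomcode import synthetic


@pytest.fixture
def small_truth():
    """A compact noise-free movie ground truth with 4 spots and 3 stimuli."""
    amps = np.array(
        [
            [0.05, 0.0, 0.02, 0.0],
            [0.0, 0.08, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return synthetic.MovieGroundTruth(
        baseline_map=synthetic.make_baseline_map((80, 100), seed=5),
        spot_centers=((20, 25), (20, 75), (60, 25), (60, 75)),
        amplitudes=amps,
        shifts=np.zeros((3, 2), dtype=int),
        spot_sigma=5.0,
        bleach_frac=0.15,
        bleach_tau=30.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
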