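import numpy as np
import pytest

from neoseg import build_feature_map
from neoseg.preprocess import BrainMask
from neoseg.synthetic import (PhantomSpec, default_specs, generate_phantom,
                              sample_training_set)


@pytest.fixture(scope="session")
def training_samples():
    """Balanced labeled samples drawn from three default training phantoms."""
    specs = default_specs(3, seed=100)
    return sample_training_set(specs, 300, seed=101)


@pytest.fixture(scope="session")
def feature_map(training_samples):
    return build_feature_map(training_samples)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom (noise, bias, PV, WMSA all on)."""
    spec = PhantomSpec(seed=1)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """High-separation phantom: no bias, no partial volume, noise SD 4
    (>= 6 SD separation between closest class means)."""
    spec = PhantomSpec(seed=2, noise_sd=4.0, bias_amplitude=0.0,
                       pv_width_vox=0.0, n_wmsa=0)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


def brain_mask_of(spec, truth):
    return BrainMask(truth.brain_mask, spec.spacing)


def rng(seed=0):
    return np.random.default_rng(seed)
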