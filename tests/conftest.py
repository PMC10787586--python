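import numpy as np
import pytest

from lattiscope import AcquisitionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_acq():
    """Small noiseless, blur-free acquisition for exact-recovery tests."""
    return AcquisitionSpec(voxel_size=(0.5, 0.5, 0.5), shape=(40, 120, 120),
                           mode="confocal", psf_sigma=(0.0, 0.0),
                           photon_scale=0.0, read_noise=0.0)


def make_acq(**kw):
    defaults = dict(voxel_size=(0.5, 0.5, 0.5), shape=(40, 120, 120),
                    mode="confocal", psf_sigma=(0.0, 0.0),
                    photon_scale=0.0, read_noise=0.0)
    defaults.update(kw)
    return AcquisitionSpec(**defaults)
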