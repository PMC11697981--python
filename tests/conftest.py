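import numpy as np
import pytest

from dnapalette import CodecConfig, SeriesSpec, generate_dicom_like


@pytest.fixture(scope="session")
def toy_config():
    """Three-oligo teaching configuration: universe {A, T, G}, no VT, no ladder."""
    return CodecConfig.toy()


@pytest.fixture(scope="session")
def small_series():
    """A small imaging-like archive plus its alignment profile."""
    spec = SeriesSpec(n_files=4, file_size=4096, diff_rate=0.01, seed=3)
    return generate_dicom_like(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
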