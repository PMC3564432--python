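import numpy as np
import pytest

from snage import (
    PipelineConfig,
    SnaGeParams,
    make_ata_signal,
    signal_to_tfr,
)


@pytest.fixture(scope="session")
def ata_signal():
    return make_ata_signal()


@pytest.fixture(scope="session")
def clean_tfr(ata_signal):
    """Preprocessed TFR of the noise-free alpha-theta-alpha simulation."""
    return signal_to_tfr(ata_signal, PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_model(rng, K, t_span=(0.0, 2.5), f_span=(0.0, 30.0), signed=False):
    """A random snaGe model whose curve stays inside the given spans."""
    t_pts = np.sort(rng.uniform(*t_span, size=K))
    f_pts = rng.uniform(*f_span, size=K)
    lo = -5.0 if signed else 0.5
    a_pts = rng.uniform(lo, 5.0, size=K)
    sigma = np.array(
        [
            rng.uniform(0.05, 1.0) * (t_span[1] - t_span[0]),
            rng.uniform(0.05, 1.0) * (f_span[1] - f_span[0]),
        ]
    )
    return SnaGeParams(
        C=rng.uniform(-1.0, 1.0),
        sigma_diag=sigma,
        peak_points=np.column_stack([t_pts, f_pts, a_pts]),
    )
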