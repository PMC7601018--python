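import numpy as np
import pytest

from mccims.io_formats import Measurement


@pytest.fixture
def make_measurement():
    """Factory for small measurements with simple axes."""

    def _make(intensity, rt_axis=None, irm_axis=None, sample_id="s1"):
        intensity = np.asarray(intensity, dtype=float)
        n_rt, n_irm = intensity.shape
        if rt_axis is None:
            rt_axis = np.arange(1.0, n_rt + 1.0)
        if irm_axis is None:
            irm_axis = np.linspace(0.1, 0.1 * n_irm, n_irm)
        return Measurement(
            sample_id=sample_id, rt_axis=rt_axis, irm_axis=irm_axis, intensity=intensity
        )

    return _make


def gaussian2d(shape, center, sigma, height=1.0):
    """2D Gaussian bump on a zero background (grid-index coordinates)."""
    i = np.arange(shape[0])[:, None]
    j = np.arange(shape[1])[None, :]
    return height * np.exp(
        -0.5 * (((i - center[0]) / sigma[0]) ** 2 + ((j - center[1]) / sigma[1]) ** 2)
    )


@pytest.fixture
def single_gaussian(make_measurement):
    """One clean wide Gaussian (sigma 6 grid points) with apex at (20, 25)."""
    x = gaussian2d((41, 51), (20, 25), (6, 6), height=1.0)
    m = make_measurement(x, rt_axis=np.arange(41, dtype=float),
                         irm_axis=np.linspace(0.01, 0.51, 51))
    return m, (20, 25)


@pytest.fixture(scope="session")
def minimal_dataset():
    """Session-cached synthetic two-class dataset (15/15, planted peaks)."""
    from mccims import synthetic_data

    spec, counts = synthetic_data.preset("minimal")
    measurements, labels, truth = synthetic_data.generate_dataset(spec, counts, seed=20240101)
    return spec, measurements, labels, truth
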