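import numpy as np
import pytest

from terrazone.terrain import FeatureMatrix, GridField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def smooth_random_dem(rng, rows=20, cols=24, cell=10.0, amplitude=2.0):
    """A smooth synthetic DEM: sum of low-frequency sinusoids plus a tilt."""
    y, x = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    phase = rng.uniform(0, 2 * np.pi, 4)
    z = (
        amplitude * np.sin(2 * np.pi * x / cols + phase[0])
        + 0.7 * amplitude * np.cos(2 * np.pi * y / rows + phase[1])
        + 0.4 * amplitude * np.sin(2 * np.pi * (x + y) / (rows + cols) + phase[2])
        + 0.01 * cell * x
        + 0.005 * cell * y
    )
    return GridField(z, 0.0, 0.0, cell, attribute_name="elevation", units="m")


@pytest.fixture
def random_dem(rng):
    return smooth_random_dem(rng)


def feature_matrix_from_array(data, normalized=False):
    """Wrap a bare array as a FeatureMatrix with dummy grid bookkeeping."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    loc = np.column_stack([np.arange(n), np.zeros(n, dtype=int)])
    norm = {"mean": np.zeros(k), "std": np.ones(k)} if normalized else None
    return FeatureMatrix(
        data, tuple(f"f{i}" for i in range(k)), loc, normalization=norm
    )
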