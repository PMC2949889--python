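import numpy as np
import pytest

from hawkestre.data import MarkedPointDataset, Window
from hawkestre.splines import SplineSpec


@pytest.fixture
def tiny_dataset():
    """Two windows, two marks, one covariate; hand-placed points."""
    windows = [Window("chr1", 0.0, 10_000.0, 0), Window("chr2", 0.0, 8_000.0, 1)]
    ds = MarkedPointDataset(
        windows=windows,
        marks=("A", "B"),
        covariate_names=("cov",),
    )
    ds.points[(0, "A")] = np.array([500.0, 1200.0, 4000.0, 7000.0])
    ds.points[(0, "B")] = np.array([700.0, 1500.0, 6500.0])
    ds.points[(1, "A")] = np.array([300.0, 2500.0])
    ds.points[(1, "B")] = np.array([900.0, 3100.0, 5000.0])
    ds.covariates[(0, "cov")] = (np.array([2000.0, 6000.0]), np.array([3000.0, 6400.0]))
    ds.covariates[(1, "cov")] = (np.array([100.0]), np.array([700.0]))
    ds.validate()
    return ds


@pytest.fixture
def default_spec():
    return SplineSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
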