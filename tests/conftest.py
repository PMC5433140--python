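import numpy as np
import pytest

from chromnmf import CoverageMatrix, make_bins


@pytest.fixture
def toy_bins():
    """Two small chromosomes, fully mappable, 200-bp bins."""
    return make_bins({"chrA": 1000, "chrB": 1001}, bin_width=200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def matrix_from_values(values, marks=None, bin_width=200):
    """Wrap a plain array as a CoverageMatrix on a synthetic chromosome."""
    values = np.asarray(values, dtype=float)
    marks = marks or [f"m{k}" for k in range(values.shape[1])]
    starts = np.arange(values.shape[0], dtype=np.int64) * bin_width
    return CoverageMatrix(
        values=values,
        marks=list(marks),
        bin_chroms=np.full(values.shape[0], "chrS1", dtype=object),
        bin_starts=starts,
        bin_ends=starts + bin_width,
    )


@pytest.fixture
def wrap_matrix():
    return matrix_from_values
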