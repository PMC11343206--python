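import numpy as np
import pytest

import resectseq as rs


@pytest.fixture
def chrom_sizes():
    return {"chr1": 100_000, "chr2": 50_000}


@pytest.fixture
def small_dataset():
    """A small but realistic simulated dataset shared across tests."""
    params = rs.SimParams(seed=7, n_chromosomes=2, chrom_length=200_000,
                          n_hotspots=40, total_reads=200_000)
    hotspots, track, truth = rs.simulate_endpoint_dataset(params)
    return params, hotspots, track, truth


@pytest.fixture
def small_profile(small_dataset):
    _, hotspots, track, _ = small_dataset
    matrices = rs.extract_oriented_matrix(track, hotspots)
    return rs.subtract_background(rs.average_profile(matrices))


def make_profile(values, start=-2500, **meta):
    values = np.asarray(values, dtype=float)
    positions = np.arange(start, start + values.size)
    return rs.Profile(positions, values, **meta)


@pytest.fixture
def delta_profile_factory():
    """Profile over [-2600, 2600] with deltas at given (pos, value) pairs."""

    def make(deltas, background=0.0, **meta):
        positions = np.arange(-2600, 2601)
        values = np.zeros(positions.size)
        for pos, val in deltas:
            values[pos + 2600] = val
        meta.setdefault("background", background)
        return rs.Profile(positions, values, **meta)

    return make
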