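import numpy as np
import pytest

from genotracks.core import GenomicRange, make_column_table
from genotracks.fixtures import FixtureConfig, make_datasource


def random_table(rng, n_rows, chrom="chr1", max_pos=100_000, max_len=500,
                 columns=("v",), nan_fraction=0.0, row_names=False):
    """Seeded random ColumnTable used across suites."""
    starts = rng.integers(0, max_pos, size=n_rows)
    lengths = rng.integers(1, max_len + 1, size=n_rows)
    values = {}
    for name in columns:
        col = rng.normal(size=n_rows)
        if nan_fraction:
            col[rng.random(n_rows) < nan_fraction] = np.nan
        values[name] = col
    return make_column_table(
        [chrom] * n_rows,
        starts,
        starts + lengths,
        values,
        row_names=[f"r{i}" for i in range(n_rows)] if row_names else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


@pytest.fixture
def small_table():
    return make_column_table(
        ["chr1", "chr1", "chr1", "chr2"],
        [0, 10, 30, 5],
        [10, 20, 31, 15],
        {"v": [1.0, 2.0, 4.0, 8.0]},
    )


@pytest.fixture(scope="session")
def fixture_config():
    # desk-scale variant of the defaults; keeps the full suite fast
    return FixtureConfig(
        seed=42,
        n_chroms=2,
        chrom_length=1_000_000,
        n_genes=20,
        signal_step=500,
        n_peaks=50,
        n_features=60,
        n_samples=6,
        group_effect=2.0,
    )


@pytest.fixture(scope="session")
def fixture_source(fixture_config):
    return make_datasource(fixture_config)


@pytest.fixture
def whole_region(fixture_config):
    return GenomicRange("chr1", 0, fixture_config.chrom_length)
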