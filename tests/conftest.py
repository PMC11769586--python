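import numpy as np
import pandas as pd
import pytest

from dosagescan.refbuild import Chromosome, SubgenomeRegistry
from dosagescan.coverage import WINDOW_COLUMNS


@pytest.fixture
def registry_100k():
    """Two homoeolog pairs of 100 kb chromosomes."""
    return SubgenomeRegistry(
        [
            Chromosome("A01", 100_000, "A"),
            Chromosome("A02", 100_000, "A"),
            Chromosome("C1", 100_000, "C"),
            Chromosome("C2", 100_000, "C"),
        ],
        [("A01", "C1"), ("A02", "C2")],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_window_table(rows):
    """rows: (chrom, start, end, masked_fraction, D, excluded, score)."""
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


@pytest.fixture
def window_table_factory():
    return make_window_table
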