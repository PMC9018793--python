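import numpy as np
import pandas as pd
import pytest

from epidmr.genome import GenomeDef
from epidmr.windows import make_windows


@pytest.fixture
def small_genome() -> GenomeDef:
    """Two chromosomes, 30 kb + 12.5 kb, with a few fixed CpG positions."""
    return GenomeDef(
        ["chr1", "chr2"], [30_000, 12_500],
        {"chr1": np.arange(100, 3000, 97), "chr2": np.arange(50, 12_000, 311)},
    )


@pytest.fixture
def small_grid(small_genome):
    return make_windows(small_genome, window_size=1000)


def stats_frame(pvals, chrom="chr1", window_size=1000, start0=0):
    """Position-sorted single-chromosome WindowStat table from p values."""
    n = len(pvals)
    starts = start0 + np.arange(n, dtype=np.int64) * window_size
    return pd.DataFrame({
        "window": np.arange(n), "chrom": chrom,
        "start": starts, "end": starts + window_size,
        "mean_A": 1.0, "mean_B": 1.0, "log2fc": np.linspace(-1, 1, n),
        "pvalue": np.asarray(pvals, dtype=float),
        "qvalue": np.minimum(np.asarray(pvals, dtype=float) * n, 1.0),
    })
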