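import numpy as np
import pandas as pd
import pytest

from regulink.genomic import PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def random_peakset(rng, name="p", n=20, genome=1000, max_len=60):
    """Random (possibly overlapping) intervals on a small linear genome."""
    starts = rng.integers(0, genome - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return PeakSet(name, pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + lengths}))


def coverage_mask(peaks: PeakSet, genome=1000) -> np.ndarray:
    """Per-base boolean oracle of covered positions."""
    mask = np.zeros(genome, dtype=bool)
    for r in peaks.df.itertuples():
        mask[r.start:r.end] = True
    return mask
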