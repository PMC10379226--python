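import numpy as np
import pytest

from hervmir.annotation_io import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chroms=("chr1", "chr2"), coord_max=1000,
                     len_max=60):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, coord_max))
        length = int(rng.integers(1, len_max))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + length,
                                   str(rng.choice(["+", "-", "."]))))
    return out
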