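import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

from strandqc import AlignedTags


@pytest.fixture
def toy_tags():
    """Fixed 12-tag library on a 200-bp chromosome."""
    return AlignedTags(
        chrom_sizes={"chr1": 200},
        plus_positions={"chr1": np.array([10, 40, 40, 80, 120, 150])},
        minus_positions={"chr1": np.array([30, 60, 95, 100, 140, 170])},
        read_length=36,
    )


def random_tags(rng, n_tags=40, chrom_sizes=None, read_length=20):
    """Small random library with both strands populated on each chromosome."""
    chrom_sizes = chrom_sizes or {"chrA": 300, "chrB": 250}
    plus, minus = {}, {}
    chroms = sorted(chrom_sizes)
    per = max(n_tags // (2 * len(chroms)), 1)
    for chrom in chroms:
        size = chrom_sizes[chrom]
        plus[chrom] = np.sort(rng.integers(0, size, per))
        minus[chrom] = np.sort(rng.integers(0, size, per))
    return AlignedTags(
        chrom_sizes=chrom_sizes,
        plus_positions=plus,
        minus_positions=minus,
        read_length=read_length,
    )
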