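import numpy as np
import pandas as pd
import pytest

from cfmethylome.io import SampleMethylome


def build_methylome(rows, sample_id="s", group="custom", min_coverage=1):
    """rows: (chrom, pos, strand, context, meth, unmeth) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "meth", "unmeth"])
    return SampleMethylome(df, sample_id=sample_id, group=group,
                           min_coverage=min_coverage)


@pytest.fixture
def tiny_methylome():
    return build_methylome([
        ("chr1", 100, "+", "CpG", 8, 2),
        ("chr1", 101, "-", "CpG", 6, 4),
        ("chr1", 300, "+", "CpG", 1, 9),
        ("chr1", 500, "+", "CHH", 0, 10),
        ("chr2", 50, "+", "CpG", 5, 5),
    ])


@pytest.fixture
def random_methylome():
    rng = np.random.default_rng(42)
    n = 10_000
    pos = np.sort(rng.choice(np.arange(2, 10_000_000, 2), size=n, replace=False))
    strand = rng.choice(["+", "-"], size=n)
    # a minus-strand CpG at p anchors the CpG at p-1: offset odd positions
    return build_methylome(list(zip(
        np.where(np.arange(n) % 2 == 0, "chr1", "chr2"),
        pos + (strand == "-").astype(int),
        strand,
        ["CpG"] * n,
        rng.poisson(8, n),
        rng.poisson(4, n),
    )))
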