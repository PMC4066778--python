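import numpy as np
import pytest

from dbregions.core import ExperimentDesign, GenomicInterval, ReadLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(20140915)


@pytest.fixture
def two_by_two_design():
    return ExperimentDesign(
        group=["g1", "g1", "g2", "g2"], lib_size=np.full(4, 1e6)
    )


def make_library(label, reads):
    """Build a ReadLibrary from (chrom, pos5, strand) tuples."""
    return ReadLibrary(
        label,
        [r[0] for r in reads],
        [r[1] for r in reads],
        [r[2] for r in reads],
    )


def iv(start, end, chrom="chrSim"):
    return GenomicInterval(chrom, start, end)
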