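import numpy as np
import pytest

from capture3c.genomic_io import AlignedEnd, ChromSizes, GenomicInterval
from capture3c.bait_definition import BaitRegion
from capture3c.read_processing import make_pet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000})


@pytest.fixture
def bait():
    # 2500 bp bait in the middle of chr1
    return BaitRegion(
        GenomicInterval("chr1", 5_000_000, 5_002_500), 5_001_250, "heuristic"
    )


def end(read_id, chrom, pos, strand="+", mapq=42):
    return AlignedEnd(read_id, chrom, pos, strand, mapq)


def pet(read_id, chrom1, pos1, chrom2, pos2, strand1="+", strand2="+", mapq=42):
    return make_pet(
        end(read_id, chrom1, pos1, strand1, mapq),
        end(read_id, chrom2, pos2, strand2, mapq),
    )


@pytest.fixture
def make_end():
    return end


@pytest.fixture
def make_simple_pet():
    return pet
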