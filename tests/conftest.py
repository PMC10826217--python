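import numpy as np
import pytest

from otsucall.profile import RDProfile


def make_piecewise(lengths, levels, bin_size=1000, chrom="chr1"):
    """Noiseless piecewise-constant profile with known breakpoints."""
    vals = np.concatenate([np.full(L, lv, dtype=float) for L, lv in zip(lengths, levels)])
    truth = np.cumsum(lengths)[:-1]
    return RDProfile(chrom, bin_size, vals), truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_bam(tmp_path):
    """Write a small coordinate-sorted, indexed BAM with known read placements.

    Returns (bam_path, reads) where reads is a list of (start, end) aligned
    spans on contig 'tig' of length 100.
    """
    import pysam

    reads = [(10, 15), (5, 10), (7, 12), (50, 80)]
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "tig", "LN": 100}]}
    path = tmp_path / "tiny.bam"
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (s, e) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.query_sequence = "A" * (e - s)
            a.reference_id = 0
            a.reference_start = s
            a.cigarstring = f"{e - s}M"
            a.mapping_quality = 60
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))
    return path, reads
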