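import numpy as np
import pysam
import pytest

from covplot.regions import GenomicRegion
from covplot.simulate import make_demo_bundle


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Full synthetic demo dataset, generated once per test session."""
    outdir = tmp_path_factory.mktemp("demo")
    manifest = make_demo_bundle(outdir, seed=0)
    return outdir, manifest


@pytest.fixture(scope="session")
def demo_dir(demo_bundle):
    return demo_bundle[0]


@pytest.fixture(scope="session")
def demo_manifest(demo_bundle):
    return demo_bundle[1]


def write_bam(path, chrom, chrom_len, reads):
    """Write a sorted indexed BAM from (start, cigar_blocks) tuples.

    Each read is a list of (start, end) reference blocks; consecutive
    blocks are joined by N (skip) operations. Sequences are arbitrary A's.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda blocks: blocks[0][0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i, blocks in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            qlen = sum(e - s for s, e in blocks)
            a.query_sequence = "A" * qlen
            a.flag = 0
            a.reference_id = 0
            a.reference_start = blocks[0][0]
            a.mapping_quality = 60
            cigar = []
            for k, (s, e) in enumerate(blocks):
                if k > 0:
                    cigar.append((3, s - blocks[k - 1][1]))
                cigar.append((0, e - s))
            a.cigar = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(a)
    pysam.index(str(path))
    return path


def brute_force_depth(region: GenomicRegion, reads) -> np.ndarray:
    """Independent pileup oracle: expand every covered block into
    per-position increments."""
    depth = np.zeros(len(region))
    for blocks in reads:
        for s, e in blocks:
            for pos in range(max(s, region.start), min(e, region.end)):
                depth[pos - region.start] += 1
    return depth
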