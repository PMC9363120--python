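"""Shared fixtures: tiny synthetic alignment files built at test time."""

from __future__ import annotations

import pysam
import pytest

CHROM = "chr1"
CHROM_LEN = 1_000_000

HEADER = {
    "HD": {"VN": "1.6", "SO": "coordinate"},
    "SQ": [{"SN": CHROM, "LN": CHROM_LEN}],
}


def make_pair(name: str, pos: int, tlen: int, mapq: int = 60,
              read_len: int = 50, cigar1: str | None = None,
              cigar2: str | None = None, seq1: str | None = None,
              seq2: str | None = None, proper: bool = True,
              chrom_id: int = 0):
    """Build a coordinate-sorted proper read pair with the given template length.

    ``pos`` is the 0-based leftmost position; mate 2 is placed so that the
    fragment spans exactly ``tlen`` bases.
    """
    a = pysam.AlignedSegment()
    a.query_name = name
    a.query_sequence = seq1 or "A" * read_len
    a.reference_id = chrom_id
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar1 or f"{read_len}M"
    a.flag = 0x1 | 0x40 | 0x20 | (0x2 if proper else 0)
    a.template_length = tlen
    a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))

    b = pysam.AlignedSegment()
    b.query_name = name
    b.query_sequence = seq2 or "A" * read_len
    b.reference_id = chrom_id
    b.reference_start = pos + tlen - read_len
    b.mapping_quality = mapq
    b.cigarstring = cigar2 or f"{read_len}M"
    b.flag = 0x1 | 0x80 | 0x10 | (0x2 if proper else 0)
    b.template_length = -tlen
    b.query_qualities = pysam.qualitystring_to_array("I" * len(b.query_sequence))

    a.next_reference_id = b.reference_id
    a.next_reference_start = b.reference_start
    b.next_reference_id = a.reference_id
    b.next_reference_start = a.reference_start
    return a, b


def write_bam(path, reads, header: dict | None = None) -> str:
    """Write reads to a sorted, indexed BAM; returns the path as str."""
    path = str(path)
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header or HEADER) as fh:
        for read in reads:
            fh.write(read)
    pysam.sort("-o", path, unsorted)
    pysam.index(path)
    return path


@pytest.fixture
def simple_bam(tmp_path):
    """Three clean pairs at lengths 166, 166, 320."""
    reads = []
    for i, (pos, tlen) in enumerate([(100, 166), (500, 166), (900, 320)]):
        reads.extend(make_pair(f"frag{i}", pos, tlen))
    return write_bam(tmp_path / "simple.bam", reads)
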