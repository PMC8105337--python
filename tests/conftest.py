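"""Shared fixtures: hand-built alignment records and small architectures."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from myelotrace import syndata
from myelotrace.syndata import Variant


@pytest.fixture(scope="session")
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chr1", "LN": 100_000}],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    name: str,
    pos0: int,
    cigar: str,
    bases: dict[int, str] | None = None,
    flag: int = 0,
    mapq: int = 60,
    cell: str | None = "CELL1",
    umi: str | None = None,
    chrom: str = "chr1",
) -> pysam.AlignedSegment:
    """Build an aligned read whose sequence is all-A except the bases
    explicitly placed at given *reference* positions (0-based)."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = header.references.index(chrom)
    a.reference_start = pos0
    a.mapping_quality = mapq
    a.cigarstring = cigar
    qlen = a.infer_query_length() or 0
    seq = ["A"] * qlen
    if bases and not (flag & 0x4):
        ref2q = {
            rpos: qpos
            for qpos, rpos in a.get_aligned_pairs(matches_only=True)
        }
        for rpos, base in bases.items():
            seq[ref2q[rpos]] = base
    a.query_sequence = "".join(seq)
    a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    if cell is not None:
        a.set_tag("CB", cell)
    a.set_tag("UB", umi if umi is not None else f"UMI-{name}")
    return a


@pytest.fixture(scope="session")
def two_snvs() -> list[Variant]:
    return [
        Variant("v1", "chr1", 100, "A", "G"),  # 0-based 99
        Variant("v2", "chr1", 150, "C", "T"),  # 0-based 149
    ]


@pytest.fixture(scope="session")
def twenty_read_fixture(sam_header, two_snvs):
    """Twenty reads over two SNVs with hand-enumerated expected output.

    Exercises plain matches, a deletion spanning the locus, soft clips,
    an insertion, low MAPQ, duplicate/secondary/unmapped flags, a
    missing cell tag, a third-allele base, and reads covering neither
    locus.
    """
    H = sam_header
    reads = [
        # covering v1 only
        make_read(H, "r01", 59, "50M", {99: "A"}),                 # v1 ref
        make_read(H, "r02", 59, "50M", {99: "G"}, cell="CELL2"),   # v1 alt
        # covering both loci
        make_read(H, "r03", 59, "100M", {99: "G", 149: "T"}),      # both alt
        # deletion spans v1; aligned at v2
        make_read(H, "r04", 89, "10M20D40M", {149: "C"}),          # v2 ref only
        # soft clip before the aligned block
        make_read(H, "r05", 95, "30S20M", {99: "A"}),              # v1 ref
        # skipped reads
        make_read(H, "r06", 90, "20M", {99: "G"}, mapq=5),
        make_read(H, "r07", 90, "20M", {99: "G"}, flag=0x400),     # duplicate
        make_read(H, "r08", 90, "20M", {99: "G"}, flag=0x100),     # secondary
        make_read(H, "r09", 90, "20M", flag=0x4),                  # unmapped
        make_read(H, "r10", 90, "20M", {99: "G"}, cell=None),      # no CB tag
        # third allele
        make_read(H, "r11", 90, "20M", {99: "C"}),                 # v1 other
        # covering v2 only
        make_read(H, "r12", 140, "20M", {149: "T"}, cell="CELL2"),  # v2 alt
        make_read(H, "r13", 0, "20M"),                             # covers none
        # insertion before v1
        make_read(H, "r14", 95, "10M5I10M", {99: "A"}),            # v1 ref
        make_read(H, "r15", 140, "20M", {149: "C"}),               # v2 ref
        make_read(H, "r16", 140, "20M", {149: "C"}, cell="CELL3"),  # v2 ref
        make_read(H, "r17", 95, "10M", {99: "G"}, cell="CELL3"),   # v1 alt
        # two reads sharing one UMI (both alt) for UMI collapse
        make_read(H, "r18", 90, "20M", {99: "G"}, cell="CELL3", umi="UMI-S"),
        make_read(H, "r19", 90, "20M", {99: "G"}, cell="CELL3", umi="UMI-S"),
        make_read(H, "r20", 200, "50M"),                           # covers none
    ]
    expected = {
        ("v1", "CELL1", "UMI-r01", "ref", "r01"),
        ("v1", "CELL2", "UMI-r02", "alt", "r02"),
        ("v1", "CELL1", "UMI-r03", "alt", "r03"),
        ("v2", "CELL1", "UMI-r03", "alt", "r03"),
        ("v2", "CELL1", "UMI-r04", "ref", "r04"),
        ("v1", "CELL1", "UMI-r05", "ref", "r05"),
        ("v1", "CELL1", "UMI-r11", "other", "r11"),
        ("v2", "CELL2", "UMI-r12", "alt", "r12"),
        ("v1", "CELL1", "UMI-r14", "ref", "r14"),
        ("v2", "CELL1", "UMI-r15", "ref", "r15"),
        ("v2", "CELL3", "UMI-r16", "ref", "r16"),
        ("v1", "CELL3", "UMI-r17", "alt", "r17"),
        ("v1", "CELL3", "UMI-S", "alt", "r18"),
        ("v1", "CELL3", "UMI-S", "alt", "r19"),
    }
    return reads, expected


@pytest.fixture(scope="session")
def small_arch():
    """Three subclones, two timepoints, full purity (deterministic tests)."""
    return syndata.gen_architecture(
        7, n_subclones=3, n_timepoints=2, n_variants=9, purity=[1.0, 1.0]
    )
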