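"""Fragment-length extraction from paired-end cfDNA alignments.

Builds per-sample length histograms from coordinate-sorted BAM files. A
fragment is counted once per read pair, at the absolute template length
reported by the aligner, after filtering on mapping quality, soft/hard
clipping, excluded genomic regions and a length window. Also supports
splitting the fragments overlapping a somatic variant locus into
mutation-carrying and wild-type histograms, which lets the tumor-derived
length distribution be observed directly.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pysam
from intervaltree import IntervalTree

from .histograms import (DEFAULT_MAX_LENGTH, DEFAULT_MIN_LENGTH,
                         LengthHistogram, default_grid)

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentFilterConfig",
    "FilterCounters",
    "VariantLocus",
    "load_excluded_regions",
    "extract_fragment_lengths",
    "split_lengths_at_variant",
    "read_variant_table",
]

_VALID_BASES = frozenset("ACGT")


def variant_position_to_zero_based(position_1based: int) -> int:
    """Single place where 1-based variant coordinates meet 0-based BAM/BED."""
    return position_1based - 1


@dataclass
class FragmentFilterConfig:
    """Read-pair filters applied before counting a fragment length.

    ``excluded_regions`` maps chromosome name to an IntervalTree of 0-based
    half-open intervals; a pair is rejected when either mate's alignment
    overlaps any excluded interval by at least one base.
    ``allow_merged_single_end`` additionally accepts single-end records
    (e.g. adapter-merged read pairs reconstructed upstream) whose fragment
    length is the query length.
    """

    min_mapq: int = 30
    min_length: int = DEFAULT_MIN_LENGTH
    max_length: int = DEFAULT_MAX_LENGTH
    excluded_regions: dict[str, IntervalTree] = field(default_factory=dict)
    reject_clipped: bool = True
    allow_merged_single_end: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("require 0 < min_length <= max_length")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def grid(self):
        return default_grid(self.min_length, self.max_length)


@dataclass
class FilterCounters:
    """Per-filter rejection bookkeeping; kept + rejections = total pairs."""

    total_pairs: int = 0
    kept: int = 0
    fail_not_proper: int = 0
    fail_mapq: int = 0
    fail_clipped: int = 0
    fail_excluded: int = 0
    fail_length: int = 0
    single_end_skipped: int = 0
    unmatched_mates: int = 0
    skipped_chromosome: int = 0

    def rejected(self) -> int:
        return (self.fail_not_proper + self.fail_mapq + self.fail_clipped
                + self.fail_excluded + self.fail_length)


@dataclass
class VariantLocus:
    """A single-nucleotide somatic variant, 1-based as in VCF."""

    chromosome: str
    position: int
    reference: str
    alternate: str

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        self.alternate = self.alternate.upper()
        if self.reference not in _VALID_BASES or self.alternate not in _VALID_BASES:
            raise ValueError("alleles must be single bases in {A,C,G,T}")
        if self.reference == self.alternate:
            raise ValueError("reference and alternate alleles are identical")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


def load_excluded_regions(bed_path: str) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def read_variant_table(path: str) -> list[VariantLocus]:
    """Read a CHROM/POS/REF/ALT tab-separated variant table."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("CHROM"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            loci.append(VariantLocus(chrom, int(pos), ref, alt))
    return loci


def _open_alignment(path: str) -> pysam.AlignmentFile:
    if not os.path.exists(path):
        raise IOError(f"alignment file not found: {path}")
    af = pysam.AlignmentFile(path)
    if af.is_bam or af.is_cram:
        try:
            af.check_index()
        except (ValueError, AttributeError) as exc:
            raise IOError(f"alignment file {path} has no index") from exc
    return af


def _is_clipped(read: pysam.AlignedSegment) -> bool:
    return any(op in (4, 5) for op, _ in (read.cigartuples or []))


def _overlaps_excluded(read: pysam.AlignedSegment,
                       trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(read.reference_name)
    if tree is None:
        return False
    end = read.reference_end
    return end is not None and tree.overlaps(read.reference_start, end)


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.is_qcfail)


def _iter_fragments(af: pysam.AlignmentFile, filters: FragmentFilterConfig,
                    counters: FilterCounters):
    """Yield retained fragments as (mates, length) with mates a 1- or 2-tuple.

    Pairs are matched by query name across the coordinate-sorted stream; the
    filters are applied jointly to both mates and each pair is counted once.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    saw_paired = False
    for read in af:
        if not _usable(read):
            continue
        if not read.is_paired:
            if filters.allow_merged_single_end:
                counters.total_pairs += 1
                length = read.query_length
                keep, _ = _pair_passes((read,), length, filters, counters)
                if keep:
                    yield (read,), length
            else:
                counters.single_end_skipped += 1
            continue
        saw_paired = True
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
            continue
        counters.total_pairs += 1
        first, second = (mate, read) if mate.reference_start <= read.reference_start \
            else (read, mate)
        if not (first.is_proper_pair and second.is_proper_pair):
            counters.fail_not_proper += 1
            continue
        length = abs(first.template_length)
        keep, _ = _pair_passes((first, second), length, filters, counters)
        if keep:
            yield (first, second), length
    counters.unmatched_mates += len(pending)
    if not saw_paired and counters.single_end_skipped and \
            not filters.allow_merged_single_end:
        raise IOError(
            "alignment file contains only single-end reads; pass "
            "allow_merged_single_end=True if these are merged read pairs")


def _pair_passes(mates, length: int, filters: FragmentFilterConfig,
                 counters: FilterCounters) -> tuple[bool, str]:
    """Apply filters in a fixed order so each rejection increments one counter."""
    if any(m.mapping_quality < filters.min_mapq for m in mates):
        counters.fail_mapq += 1
        return False, "mapq"
    if filters.reject_clipped and any(_is_clipped(m) for m in mates):
        counters.fail_clipped += 1
        return False, "clipped"
    if filters.excluded_regions and \
            any(_overlaps_excluded(m, filters.excluded_regions) for m in mates):
        counters.fail_excluded += 1
        return False, "excluded"
    if not filters.min_length <= length <= filters.max_length:
        counters.fail_length += 1
        return False, "length"
    counters.kept += 1
    return True, ""


def extract_fragment_lengths(
    alignment_file: str,
    filters: FragmentFilterConfig | None = None,
    label: str | None = None,
    return_counters: bool = False,
):
    """Build the filtered fragment-length histogram of one sample.

    Each retained read pair contributes one count at its absolute template
    length. Per-filter rejection counts are logged, and returned as well when
    ``return_counters`` is set.
    """
    filters = filters or FragmentFilterConfig()
    label = label or os.path.basename(alignment_file)
    counters = FilterCounters()
    hist = LengthHistogram(label, [0] * filters.grid().size, filters.grid())
    with _open_alignment(alignment_file) as af:
        for _, length in _iter_fragments(af, filters, counters):
            hist.add(length)
    if hist.total == 0:
        logger.warning("no fragments retained from %s", alignment_file)
    logger.info("%s: %d pairs, kept %d (%s)", label, counters.total_pairs,
                counters.kept, counters)
    if return_counters:
        return hist, counters
    return hist


def _base_at(read: pysam.AlignedSegment, ref_pos_0based: int):
    """(covers, base) at a reference position; base None means a deletion."""
    if read.reference_start is None or read.reference_end is None:
        return False, None
    if not read.reference_start <= ref_pos_0based < read.reference_end:
        return False, None
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos == ref_pos_0based:
            if qpos is None:
                return True, None
            return True, read.query_sequence[qpos].upper()
    return False, None


def split_lengths_at_variant(
    alignment_file: str,
    locus: VariantLocus,
    filters: FragmentFilterConfig | None = None,
) -> tuple[LengthHistogram, LengthHistogram]:
    """Split retained fragments covering a variant locus by the base they carry.

    Fragments whose read(s) show the alternate allele at the locus go to the
    ``mutated`` histogram, reference-allele fragments to ``wildtype``. Pairs
    showing a third allele or a deletion at the locus, or whose two mates
    disagree, are assigned to neither (counted and logged).
    """
    filters = filters or FragmentFilterConfig()
    grid = filters.grid()
    mutated = LengthHistogram(f"{locus.chromosome}:{locus.position}:mut",
                              [0] * grid.size, grid)
    wildtype = LengthHistogram(f"{locus.chromosome}:{locus.position}:wt",
                               [0] * grid.size, grid.copy())
    pos0 = variant_position_to_zero_based(locus.position)
    counters = FilterCounters()
    n_overlap = n_other = n_discordant = 0
    with _open_alignment(alignment_file) as af:
        for mates, length in _iter_fragments(af, filters, counters):
            calls = []
            for m in mates:
                if m.reference_name != locus.chromosome:
                    continue
                covers, base = _base_at(m, pos0)
                if covers:
                    calls.append(base)
            if not calls:
                continue
            n_overlap += 1
            if None in calls:          # deletion over the locus
                n_other += 1
                continue
            if len(set(calls)) > 1:    # mates disagree
                n_discordant += 1
                continue
            base = calls[0]
            if base == locus.alternate:
                mutated.add(length)
            elif base == locus.reference:
                wildtype.add(length)
            else:
                n_other += 1
    if n_overlap == 0:
        logger.warning("no retained fragment covers %s:%d",
                       locus.chromosome, locus.position)
    if n_other or n_discordant:
        logger.info("locus %s:%d: %d third-allele/deletion, %d mate-discordant "
                    "fragments set aside", locus.chromosome, locus.position,
                    n_other, n_discordant)
    return mutated, wildtype
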