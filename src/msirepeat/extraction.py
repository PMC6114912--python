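"""Convert aligned paired-end amplicon reads into marker observations.

For every read pair over a marker's amplicon the repeat-length deviation
is computed from the CIGAR string (inserted minus deleted bases whose
reference placement intersects the repeat interval) on each mate
independently; a pair contributes one count to the marker histogram only
when both mates agree ("concordant in both orientations").  Pairs that
additionally cover a flanking SNP concordantly with a ref or alt base
contribute to that SNP's allele-stratified histogram.  An observation is
usable when at least 20 concordant pairs cover the repeat.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Iterable

import numpy as np
import pysam

from .datamodel import (
    LengthHistogram,
    MarkerDefinition,
    MarkerObservation,
    NotComputableError,
    SampleRecord,
    SnpDefinition,
    SnpObservation,
    call_heterozygous,  # noqa: F401  (re-exported; part of this module's API)
)

__all__ = [
    "pair_deviation",
    "snp_base",
    "extract_observation",
    "extract_sample",
    "deletion_fraction",
    "call_heterozygous",
    "bias_table",
]

# CIGAR operation codes
_CIGAR_I = 1
_CIGAR_D = 2

_SKIP_FLAGS = (
    pysam.FUNMAP
    | pysam.FSECONDARY
    | pysam.FSUPPLEMENTARY
    | pysam.FDUP
    | pysam.FQCFAIL
)


def deletion_fraction(histogram: LengthHistogram) -> float:
    """Fraction of read pairs with a negative length deviation."""
    return histogram.deletion_fraction


def _covers(segment: pysam.AlignedSegment, start0: int, end0: int) -> bool:
    """Whether the alignment's reference span contains [start0, end0)."""
    return segment.reference_start <= start0 and segment.reference_end >= end0


def pair_deviation(
    segment: pysam.AlignedSegment, marker: MarkerDefinition
) -> int | None:
    """Repeat-length deviation of one mate, or None if not fully covering.

    The mate must span the repeat plus one reference base on each side.
    The deviation is the number of inserted bases minus the number of
    deleted reference bases whose placement intersects the repeat
    interval; an insertion is attributed to the interval when it is
    anchored at or immediately before a repeat base.
    """
    rs0 = marker.repeat_start - 1  # 0-based first repeat base
    re0 = marker.repeat_end - 1  # 0-based last repeat base
    if not _covers(segment, rs0 - 1, re0 + 2):
        return None
    deviation = 0
    ref = segment.reference_start
    for op, length in segment.cigartuples:
        if op == _CIGAR_D:
            overlap = min(ref + length, re0 + 1) - max(ref, rs0)
            if overlap > 0:
                deviation -= overlap
            ref += length
        elif op == _CIGAR_I:
            if rs0 - 1 <= ref - 1 <= re0:  # anchored inside or just before
                deviation += length
        elif op in (0, 7, 8):  # M, =, X consume reference
            ref += length
        elif op == 3:  # N
            ref += length
    return deviation


def snp_base(segment: pysam.AlignedSegment, snp: SnpDefinition) -> str | None:
    """Base the mate reports at the SNP position, or None if uncovered."""
    pos0 = snp.position - 1
    if not _covers(segment, pos0, pos0 + 1):
        return None
    for qpos, rpos in segment.get_aligned_pairs(matches_only=False):
        if rpos == pos0:
            if qpos is None:
                return None  # deleted in the read
            return segment.query_sequence[qpos].upper()
    return None


def _usable_segment(segment: pysam.AlignedSegment) -> bool:
    return (
        not segment.flag & _SKIP_FLAGS
        and segment.is_paired
        and segment.cigartuples is not None
    )


def extract_observation(
    alignments: Iterable[pysam.AlignedSegment], marker: MarkerDefinition
) -> MarkerObservation:
    """Build a MarkerObservation from the alignments over one amplicon.

    Unmapped, secondary, supplementary, duplicate-flagged and QC-fail
    records are skipped.  Pairs whose mates disagree on the deviation
    contribute to no histogram; pairs whose mates disagree at a SNP, or
    report a non-ref non-alt base there, are excluded from that SNP's
    stratification only.
    """
    pairs: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for segment in alignments:
        if _usable_segment(segment):
            pairs[segment.query_name].append(segment)

    obs = MarkerObservation(marker.marker_id)
    for snp in marker.flanking_snps:
        obs.snp_observations[snp.snp_id] = SnpObservation(snp.snp_id)

    for mates in pairs.values():
        if len(mates) != 2:
            continue
        dev_a = pair_deviation(mates[0], marker)
        dev_b = pair_deviation(mates[1], marker)
        if dev_a is None or dev_b is None or dev_a != dev_b:
            continue
        obs.histogram.add(dev_a)
        for snp in marker.flanking_snps:
            base_a = snp_base(mates[0], snp)
            base_b = snp_base(mates[1], snp)
            if base_a is None or base_a != base_b:
                continue
            if base_a not in (snp.ref_allele, snp.alt_allele):
                continue  # sequencing error must not create phantom alleles
            snp_obs = obs.snp_observations[snp.snp_id]
            hist = snp_obs.allele_histograms.setdefault(
                base_a, LengthHistogram()
            )
            hist.add(dev_a)
    return obs


def extract_sample(
    path: str | os.PathLike,
    panel: Iterable[MarkerDefinition],
    sample_id: str | None = None,
) -> SampleRecord:
    """Extract observations for every panel marker from a SAM/BAM file.

    Indexed BAMs are fetched per amplicon; SAM text is read in a single
    pass with records bucketed by reference name.
    """
    path = os.fspath(path)
    mode = "rb" if path.endswith(".bam") else "r"
    panel = list(panel)
    sample = SampleRecord(sample_id or os.path.basename(path).split(".")[0])
    with pysam.AlignmentFile(path, mode) as handle:
        indexed = mode == "rb" and handle.has_index()
        if indexed:
            for marker in panel:
                lo, hi = marker.amplicon_interval
                records = handle.fetch(marker.chromosome, lo - 1, hi)
                sample.observations[marker.marker_id] = extract_observation(
                    records, marker
                )
        else:
            by_contig: dict[str, list] = defaultdict(list)
            for record in handle:
                if not record.is_unmapped:
                    by_contig[record.reference_name].append(record)
            for marker in panel:
                records = [
                    r
                    for r in by_contig.get(marker.chromosome, [])
                    if r.reference_start < marker.amplicon_interval[1]
                    and r.reference_end > marker.amplicon_interval[0] - 1
                ]
                sample.observations[marker.marker_id] = extract_observation(
                    records, marker
                )
    return sample


def bias_table(obs: MarkerObservation, snp_id: str) -> np.ndarray:
    """2x2 allelic-bias contingency table at one heterozygous SNP.

    Rows are the two SNP alleles (major first), columns are (deletion
    read pairs, non-deletion read pairs), counting only pairs that cover
    both the SNP and the repeat concordantly.  Raises
    :class:`NotComputableError` unless the SNP is called heterozygous in
    this observation.
    """
    snp_obs = obs.snp_observations.get(snp_id)
    if snp_obs is None:
        raise NotComputableError(
            f"marker {obs.marker_id}: no observation for SNP {snp_id}"
        )
    if snp_obs.heterozygous is not True:
        raise NotComputableError(
            f"marker {obs.marker_id}: SNP {snp_id} is not heterozygous "
            f"(bias not computable)"
        )
    alleles = sorted(
        snp_obs.allele_histograms,
        key=lambda a: (-snp_obs.allele_histograms[a].total, a),
    )[:2]
    table = np.zeros((2, 2), dtype=np.int64)
    for i, allele in enumerate(alleles):
        hist = snp_obs.allele_histograms[allele]
        table[i, 0] = hist.deletion_count
        table[i, 1] = hist.total - hist.deletion_count
    return table
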