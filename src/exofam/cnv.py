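"""Stage 4: CNV segment post-processing.

Read-depth segments (CNVkit-style) are screened in a fixed order: outlier
samples are removed first, then per-segment filters (significance, integer
copy number, log2 direction threshold), then exact cross-family
deduplication, then known-locus overlap annotation (annotation only, never a
drop), and finally the common-SV containment filter.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .models import CnvSegment, PedigreeFamily

DELETION = "deletion"
DUPLICATION = "duplication"

DEL_LOG2 = -0.5
DUP_LOG2 = 0.5
MAX_P = 0.05
KEPT_COPY_NUMBERS = frozenset({0, 1, 3, 4})
COMMON_SV_FREQ = 0.01

REASON_NONE = "none"
REASON_LOW_SIG = "low-significance"
REASON_NEUTRAL_CN = "neutral-copy"
REASON_SUBTHRESHOLD = "sub-threshold-log2"
REASON_DUPLICATE = "duplicate-cross-family"
REASON_COMMON_SV = "common-sv"
REASON_OUTLIER = "outlier-sample"


@dataclass
class CnvCall:
    segment: CnvSegment
    direction: Optional[str] = None
    dropped_reason: str = REASON_NONE
    inconsistent: bool = False
    overlaps_known_asd_locus: list[tuple[str, int]] = field(default_factory=list)
    overlaps_syndromic_locus: list[tuple[str, int]] = field(default_factory=list)

    @property
    def kept(self) -> bool:
        return self.dropped_reason == REASON_NONE


def exclude_outlier_samples(
    segments: list[CnvSegment], mad_multiplier: float = 3.0
) -> tuple[list[CnvSegment], list[str]]:
    """Exclude samples whose raw segment count exceeds median + k*MAD.

    The MAD is the raw (unscaled) median absolute deviation.  With a MAD of
    zero (all counts equal) no sample is excluded unless its count exceeds
    the median, degenerately impossible — so uniform cohorts pass untouched.
    """
    counts: dict[str, int] = {}
    for s in segments:
        counts[s.sample_id] = counts.get(s.sample_id, 0) + 1
    if not counts:
        return [], []
    values = sorted(counts.values())
    med = statistics.median(values)
    mad = statistics.median([abs(v - med) for v in values])
    bound = med + mad_multiplier * mad
    excluded = sorted(s for s, n in counts.items() if n > bound)
    retained = [s for s in segments if s.sample_id not in excluded]
    return retained, excluded


def _direction(segment: CnvSegment) -> tuple[Optional[str], bool]:
    """(direction, consistent): direction from copy number, consistency from
    the log2 threshold (deletion <= -0.5, duplication >= 0.5)."""
    if segment.copy_number < 2:
        return DELETION, segment.log2_ratio <= DEL_LOG2
    if segment.copy_number > 2:
        return DUPLICATION, segment.log2_ratio >= DUP_LOG2
    return None, False


def filter_cnv_segments(
    segments: list[CnvSegment],
    families: list[PedigreeFamily],
    dedup_tolerance_bp: int = 0,
) -> list[CnvCall]:
    """Apply the per-segment filters and cross-family deduplication.

    Keep iff p < 0.05, copy number in {0, 1, 3, 4} and the log2 ratio passes
    the direction threshold consistent with the copy number (a contradiction,
    e.g. cn=1 with positive log2, drops as sub-threshold with the
    inconsistency flagged).  Then any exact same interval+direction present in
    probands of different families drops every instance.
    """
    family_of: dict[str, str] = {}
    for fam in families:
        for m in fam.members:
            family_of[m.individual_id] = fam.family_id

    calls: list[CnvCall] = []
    for seg in segments:
        direction, consistent = _direction(seg)
        call = CnvCall(segment=seg, direction=direction)
        if seg.p_value >= MAX_P:
            call.dropped_reason = REASON_LOW_SIG
        elif seg.copy_number not in KEPT_COPY_NUMBERS:
            call.dropped_reason = REASON_NEUTRAL_CN
        elif not consistent:
            call.dropped_reason = REASON_SUBTHRESHOLD
            call.inconsistent = (
                direction == DELETION and seg.log2_ratio >= DUP_LOG2
            ) or (direction == DUPLICATION and seg.log2_ratio <= DEL_LOG2)
        calls.append(call)

    # cross-family exact dedup among surviving calls
    def bucket(call: CnvCall) -> tuple:
        s = call.segment
        if dedup_tolerance_bp > 0:
            t = dedup_tolerance_bp
            return (s.chrom, s.start // t, s.end // t, call.direction)
        return (s.chrom, s.start, s.end, call.direction)

    groups: dict[tuple, list[CnvCall]] = {}
    for call in calls:
        if call.kept:
            groups.setdefault(bucket(call), []).append(call)
    for group in groups.values():
        fams = {family_of.get(c.segment.sample_id, c.segment.sample_id) for c in group}
        if len(fams) > 1:
            for c in group:
                c.dropped_reason = REASON_DUPLICATE
    return calls


def _build_tree(loci: list[dict]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        trees.setdefault(locus["chrom"], IntervalTree()).addi(
            locus["start"], locus["end"], locus["locus_id"]
        )
    return trees


def annotate_known_loci(
    calls: list[CnvCall],
    asd_loci: list[dict],
    syndromic_loci: list[dict],
) -> list[CnvCall]:
    """Record >= 1 bp intersections with known ASD and syndromic CNV loci.

    Purely annotation: overlap never drops a call.  Each overlap is recorded
    as (locus_id, overlap_bp).
    """
    asd_trees = _build_tree(asd_loci)
    syn_trees = _build_tree(syndromic_loci)
    for call in calls:
        seg = call.segment
        for trees, target in (
            (asd_trees, call.overlaps_known_asd_locus),
            (syn_trees, call.overlaps_syndromic_locus),
        ):
            target.clear()
            tree = trees.get(seg.chrom)
            if tree is None:
                continue
            for iv in sorted(tree.overlap(seg.start, seg.end)):
                overlap_bp = min(seg.end, iv.end) - max(seg.start, iv.begin)
                if overlap_bp >= 1:
                    target.append((iv.data, overlap_bp))
    return calls


def apply_sv_frequency_filter(
    calls: list[CnvCall],
    sv_table: list[dict],
    require_type_match: bool = True,
) -> list[CnvCall]:
    """Drop a kept call iff its interval is completely contained within a
    structural variant of frequency > 1% (same type as the call's direction
    by default: DEL for deletions, DUP for duplications)."""
    type_of = {DELETION: "DEL", DUPLICATION: "DUP"}
    common = [sv for sv in sv_table if sv["frequency"] > COMMON_SV_FREQ]
    for call in calls:
        if not call.kept:
            continue
        seg = call.segment
        for sv in common:
            if sv["chrom"] != seg.chrom:
                continue
            if require_type_match and sv["svtype"] != type_of.get(call.direction):
                continue
            if sv["start"] <= seg.start and seg.end <= sv["end"]:
                call.dropped_reason = REASON_COMMON_SV
                break
    return calls


def run_cnv_pipeline(
    segments: list[CnvSegment],
    families: list[PedigreeFamily],
    asd_loci: list[dict],
    syndromic_loci: list[dict],
    sv_table: list[dict],
    mad_multiplier: float = 3.0,
) -> tuple[list[CnvCall], list[str]]:
    """Full CNV post-processing; returns (all calls incl. dropped, excluded
    samples).  Segments from excluded samples appear as outlier-sample drops."""
    retained, excluded = exclude_outlier_samples(segments, mad_multiplier=mad_multiplier)
    calls = filter_cnv_segments(retained, families)
    annotate_known_loci(calls, asd_loci, syndromic_loci)
    apply_sv_frequency_filter(calls, sv_table)
    outlier_calls = [
        CnvCall(segment=s, direction=_direction(s)[0], dropped_reason=REASON_OUTLIER)
        for s in segments
        if s.sample_id in set(excluded)
    ]
    return calls + outlier_calls, excluded


def mean_cnv_size(calls: list[CnvCall]) -> Optional[float]:
    """Average size (end - start) over kept calls, in bp."""
    kept = [c.segment.size for c in calls if c.kept]
    return sum(kept) / len(kept) if kept else None
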