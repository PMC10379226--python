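"""Genomic-interval arithmetic: intersection, nearest distance, run merging.

All operations use 0-based half-open :class:`~hervmir.annotation_io.GenomicInterval`
coordinates, are strand-agnostic, and never pair intervals across
chromosomes. ``intersect`` is the bedtools-intersect equivalent used to
overlap mature miRNAs with repeat annotation; ``merge_run`` chains
RepeatMasker fragments of one element back into a single run.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

from .annotation_io import GenomicInterval


class OverlapRecord(NamedTuple):
    query_index: int
    subject_index: int
    overlap_bp: int


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases (0 if disjoint or on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_bp(a: GenomicInterval, b: GenomicInterval) -> float:
    """Bases strictly between two same-chromosome intervals.

    0 when they touch or overlap; ``math.inf`` across chromosomes.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def intersect(queries: Sequence[GenomicInterval],
              subjects: Sequence[GenomicInterval],
              min_overlap_bp: int = 1) -> list[OverlapRecord]:
    """All query-subject pairs overlapping by at least ``min_overlap_bp``.

    Sweep over per-chromosome start-sorted lists: subjects are activated
    while their start precedes the current query's end and retired once
    their end precedes the current query's start (valid because queries are
    visited in start order). Output is sorted by (query_index,
    subject_index), matching the all-pairs result exactly.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom_q: dict[str, list[int]] = {}
    by_chrom_s: dict[str, list[int]] = {}
    for i, q in enumerate(queries):
        by_chrom_q.setdefault(q.chrom, []).append(i)
    for j, s in enumerate(subjects):
        by_chrom_s.setdefault(s.chrom, []).append(j)
    records: list[OverlapRecord] = []
    for chrom, q_idx in by_chrom_q.items():
        s_idx = by_chrom_s.get(chrom)
        if not s_idx:
            continue
        q_idx = sorted(q_idx, key=lambda i: queries[i].start)
        s_idx = sorted(s_idx, key=lambda j: subjects[j].start)
        active: list[int] = []
        ptr = 0
        for i in q_idx:
            q = queries[i]
            while ptr < len(s_idx) and subjects[s_idx[ptr]].start < q.end:
                active.append(s_idx[ptr])
                ptr += 1
            active = [j for j in active if subjects[j].end > q.start]
            for j in active:
                ov = min(q.end, subjects[j].end) - max(q.start, subjects[j].start)
                if ov >= min_overlap_bp:
                    records.append(OverlapRecord(i, j, ov))
    records.sort()
    return records


def nearest_distance(query: GenomicInterval,
                     subjects: Sequence[GenomicInterval]) -> float:
    """Smallest gap (bp) between ``query`` and any same-chromosome subject.

    0 if any subject touches or overlaps the query; ``math.inf`` if no
    subject shares the chromosome.
    """
    best = math.inf
    for s in subjects:
        d = gap_bp(query, s)
        if d < best:
            best = d
            if best == 0:
                break
    return best


@dataclasses.dataclass(frozen=True)
class MergedRun:
    """A chain of fragments merged across gaps <= ``gap_max``.

    ``member_length_sum`` is the summed fragment length, which stays at or
    below the span length whenever the members are mutually disjoint (the
    RepeatMasker-fragment case).
    """

    interval: GenomicInterval          # genomic span of the run
    member_indices: tuple[int, ...]    # indices into the input list
    member_length_sum: int             # summed fragment lengths, not span


def merge_run(features: Sequence[GenomicInterval], gap_max: int) -> list[MergedRun]:
    """Chain start-sorted fragments while the inter-fragment gap <= ``gap_max``.

    Input must come from a single chromosome (one strand group by caller
    convention); mixed chromosomes are a fatal error. The run length
    reported is the sum of member lengths, robust to nested insertions
    inflating the genomic span.
    """
    if not features:
        return []
    chroms = {f.chrom for f in features}
    if len(chroms) > 1:
        raise ValueError(f"merge_run requires one chromosome, got {sorted(chroms)}")
    order = sorted(range(len(features)),
                   key=lambda i: (features[i].start, features[i].end))
    runs: list[MergedRun] = []
    members = [order[0]]
    run_end = features[order[0]].end
    for i in order[1:]:
        f = features[i]
        if f.start - run_end <= gap_max:
            members.append(i)
            run_end = max(run_end, f.end)
        else:
            runs.append(_make_run(features, members))
            members = [i]
            run_end = f.end
    runs.append(_make_run(features, members))
    return runs


def _make_run(features: Sequence[GenomicInterval], members: list[int]) -> MergedRun:
    start = min(features[i].start for i in members)
    end = max(features[i].end for i in members)
    strand = features[members[0]].strand
    return MergedRun(
        GenomicInterval(features[members[0]].chrom, start, end, strand),
        tuple(members),
        sum(features[i].length for i in members))
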