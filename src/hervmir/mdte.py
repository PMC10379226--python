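"""Calling miRNAs derived from transposable elements (MDTEs).

A mature miRNA whose genomic locus overlaps a repeat-annotation record is
an MDTE; the overlapping repeat's subfamily/class/family labels classify
the call. Downstream filters restrict calls to the endogenous-retrovirus
families of interest (ERV1, ERVK, ERVL — dropping ERVL-MaLR and Gypsy) and
select subfamilies such as HERV-H-int and the LTR7 group.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections import Counter
from typing import Iterable, Sequence

from . import intervals
from .annotation_io import (GenomicInterval, HervMirnaRow, MirnaFeature,
                            RepeatFeature)

logger = logging.getLogger(__name__)

#: ERV families retained by :func:`filter_herv` (compared case-insensitively).
HERV_FAMILIES = frozenset({"erv1", "ervk", "ervl"})


@dataclasses.dataclass(frozen=True)
class MdteCall:
    """One miRNA-repeat overlap, labelled with the repeat's classification.

    ``ambiguous`` marks miRNAs overlapping more than one repeat;
    ``primary`` marks, per miRNA, the call with the largest overlap
    (ties broken toward the leftmost repeat).
    """

    mirna: MirnaFeature
    repeat: RepeatFeature
    overlap_bp: int
    family: str
    subfamily: str
    ambiguous: bool = False
    primary: bool = True

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


def call_mdtes(mirnas: Sequence[MirnaFeature],
               repeats: Sequence[RepeatFeature],
               min_overlap_bp: int = 1,
               full_containment: bool = False) -> list[MdteCall]:
    """Intersect mature miRNAs with repeat annotation.

    One call is produced per overlapping (miRNA, repeat) pair; a miRNA
    overlapping several repeats yields several calls flagged ambiguous.
    ``full_containment`` additionally requires the mature miRNA to lie
    entirely inside the repeat. Output order is deterministic
    (miRNA index, repeat index).
    """
    hits = intervals.intersect([m.interval for m in mirnas],
                               [r.interval for r in repeats],
                               min_overlap_bp=min_overlap_bp)
    if full_containment:
        hits = [h for h in hits
                if h.overlap_bp == mirnas[h.query_index].interval.length]
    per_mirna: dict[int, list[intervals.OverlapRecord]] = {}
    for h in hits:
        per_mirna.setdefault(h.query_index, []).append(h)
    calls: list[MdteCall] = []
    for qi in sorted(per_mirna):
        group = per_mirna[qi]
        ambiguous = len(group) > 1
        best = max(group, key=lambda h: (h.overlap_bp,
                                         -repeats[h.subject_index].interval.start))
        for h in group:
            rep = repeats[h.subject_index]
            calls.append(MdteCall(
                mirna=mirnas[qi], repeat=rep, overlap_bp=h.overlap_bp,
                family=rep.rep_family, subfamily=rep.rep_name,
                ambiguous=ambiguous, primary=(h is best)))
    return calls


def filter_herv(calls: Iterable[MdteCall],
                families: frozenset[str] = HERV_FAMILIES) -> list[MdteCall]:
    """Retain calls from the ERV1/ERVK/ERVL families.

    ERVL-MaLR and Gypsy calls — and any unknown family label — are dropped
    (unknown labels with a logged notice). Matching is case-insensitive on
    the full family name, so "ERVL-MaLR" does not match "ERVL".
    """
    kept: list[MdteCall] = []
    for call in calls:
        fam = call.family.lower()
        if fam in families:
            kept.append(call)
        elif fam not in ("ervl-malr", "gypsy"):
            logger.info("dropping call %s: family %r not a HERV family",
                        call.mirna.mirna_id, call.family)
    return kept


def primary_calls(calls: Iterable[MdteCall]) -> list[MdteCall]:
    """The per-miRNA primary call (largest overlap, leftmost on ties)."""
    return [c for c in calls if c.primary]


def tally_families(calls: Iterable[MdteCall]) -> tuple[Counter, Counter]:
    """Family and subfamily counts over per-miRNA primary calls."""
    prim = primary_calls(calls)
    return (Counter(c.family for c in prim),
            Counter(c.subfamily for c in prim))


def _pattern_matches(pattern: str, subfamily: str) -> bool:
    if pattern.endswith("*"):
        # prefix plus at most one letter: LTR7* hits LTR7/LTR7B/LTR7C/LTR7Y
        # but not LTR70 or LTR7B2.
        return re.fullmatch(re.escape(pattern[:-1]) + "[A-Za-z]?",
                            subfamily) is not None
    return subfamily == pattern


def select_by_subfamily(calls: Sequence[MdteCall],
                        name_patterns: Sequence[str]) -> list[MdteCall]:
    """Calls whose subfamily matches any literal name or ``NAME*`` pattern.

    A trailing ``*`` matches the prefix followed by at most one letter,
    so ``LTR7*`` captures the LTR7/LTR7B/LTR7C/LTR7Y group without
    spilling into numerically unrelated subfamilies like LTR70.
    """
    if not name_patterns:
        raise ValueError("name_patterns must not be empty")
    return [c for c in calls
            if any(_pattern_matches(p, c.subfamily) for p in name_patterns)]


def calls_from_herv_mirna_table(rows: Sequence[HervMirnaRow],
                                min_overlap_bp: int = 1) -> list[MdteCall]:
    """Lift the packaged HERV-miRNA coordinate table into MdteCall records.

    The table records each mature miRNA with the family/subfamily of the
    repeat it overlaps but not the repeat's own coordinates, so the
    repeat interval is represented by the miRNA locus itself and the
    overlap by the full mature length.
    """
    calls = []
    for row in rows:
        repeat = RepeatFeature(row.mirna.interval, row.subfamily,
                               "LTR", row.family)
        calls.append(MdteCall(row.mirna, repeat, row.mirna.interval.length,
                              row.family, row.subfamily))
    return calls
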