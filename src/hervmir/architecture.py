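"""Full-length provirus vs. solitary-LTR classification for HERV-H.

An intact HERV-H provirus carries a >7 kb internal coding region
(gag-pro-pol-env, annotated HERV-H-int) flanked by two LTRs of the LTR7
group. Recombination between the two LTRs deletes the internal region and
leaves a solitary LTR behind. RepeatMasker fragments one element into
several rows, so internal regions are first reassembled into runs; the
classification rules are then:

* full-length: summed internal fragment length strictly greater than
  ``int_min_len`` (default 7000 bp) with an LTR7-group feature within
  ``flank_max_gap`` of each end of the run, all on one strand;
* solitary: LTR7-group feature with length strictly inside
  (``ltr_len_min``, ``ltr_len_max``) = (435, 465) bp — a window sized to
  tolerate ~15 bp internal deletions — and no HERV-H-int within
  ``solitary_window`` (200 bp) on either side, any strand;
* anything else HERV-H is a truncated element.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

from . import intervals
from .annotation_io import GenomicInterval, RepeatFeature
from .intervals import MergedRun
from .mdte import MdteCall, _pattern_matches

#: rep_name of the HERV-H internal region in RepeatMasker annotation.
INT_NAME = "HERV-H-int"

#: LTR subfamilies associated with HERV-H.
LTR7_SUBFAMILIES = ("LTR7", "LTR7B", "LTR7C", "LTR7Y")

#: Genome-wide reference counts for the GRCh38 rmsk track under the default
#: thresholds, used only for reporting comparison tables.
REFERENCE_HG38_COUNTS = {
    "full_length": 17,
    "solitary": 931,
    "solitary_by_subfamily": {"LTR7": 680, "LTR7B": 155, "LTR7C": 69,
                              "LTR7Y": 27},
}

ORIGIN_LABELS = ("full_length", "solitary_ltr", "truncated_element")


@dataclasses.dataclass(frozen=True)
class ArchitectureConfig:
    """Thresholds of the architecture classifier (all in bp).

    ``strict_bounds`` applies the length window and internal-length
    cutoffs as strict inequalities (the default reading of "larger
    than 435 and smaller than 465" / ">7 kb"); set False for inclusive
    bounds.
    """

    int_min_len: int = 7000
    ltr_len_min: int = 435
    ltr_len_max: int = 465
    solitary_window: int = 200
    flank_max_gap: int = 200
    int_merge_gap: int = 1000
    strict_bounds: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ltr_len_min < self.ltr_len_max):
            raise ValueError("require 0 < ltr_len_min < ltr_len_max")
        for field in ("int_min_len", "solitary_window", "flank_max_gap",
                      "int_merge_gap"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")

    def header_lines(self) -> list[str]:
        """Threshold echo written into output headers."""
        return [f"# {f.name}={getattr(self, f.name)}"
                for f in dataclasses.fields(self)]


@dataclasses.dataclass(frozen=True)
class IntRun:
    """Merged HERV-H-int fragments forming one internal region."""

    interval: GenomicInterval
    member_count: int
    member_length_sum: int

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclasses.dataclass(frozen=True)
class ProvirusCall:
    """A full-length element: internal run plus 5'/3' flanking LTRs.

    ``ltr5`` is the genomically left flank, ``ltr3`` the right one.
    """

    int_run: IntRun
    ltr5: RepeatFeature
    ltr3: RepeatFeature

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.int_run.interval.chrom,
                               self.ltr5.interval.start,
                               self.ltr3.interval.end,
                               self.int_run.interval.strand)


@dataclasses.dataclass(frozen=True)
class SolitaryLtrCall:
    """An LTR7-group element isolated from any internal region."""

    ltr: RepeatFeature
    subfamily: str
    nearest_int_gap: float  # bp; math.inf when no int on the chromosome


def _is_ltr7(feature: RepeatFeature) -> bool:
    return feature.rep_name in LTR7_SUBFAMILIES


def build_int_runs(repeats: Sequence[RepeatFeature],
                   config: ArchitectureConfig | None = None) -> list[IntRun]:
    """Reassemble HERV-H-int fragments into internal-region runs.

    Fragments on one chromosome and strand are merged while the gap
    between consecutive fragments is at most ``int_merge_gap``.
    """
    config = config or ArchitectureConfig()
    ints = [r for r in repeats if r.rep_name == INT_NAME]
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for r in ints:
        groups.setdefault((r.interval.chrom, r.interval.strand), []).append(
            r.interval)
    runs: list[IntRun] = []
    for (_, _), ivs in sorted(groups.items()):
        for run in intervals.merge_run(ivs, gap_max=config.int_merge_gap):
            runs.append(IntRun(run.interval, len(run.member_indices),
                               run.member_length_sum))
    runs.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return runs


def _long_enough(run: IntRun, config: ArchitectureConfig) -> bool:
    if config.strict_bounds:
        return run.member_length_sum > config.int_min_len
    return run.member_length_sum >= config.int_min_len


def call_full_length(int_runs: Sequence[IntRun],
                     ltr_features: Sequence[RepeatFeature],
                     config: ArchitectureConfig | None = None,
                     ) -> list[ProvirusCall]:
    """Identify full-length proviruses.

    A call requires an internal run passing the length cutoff plus an
    LTR7-group feature ending within ``flank_max_gap`` upstream of the run
    and one starting within ``flank_max_gap`` downstream, all on the run's
    strand. Each LTR is assigned to at most one run — its closest
    (smallest flank gap; leftmost run on ties).
    """
    config = config or ArchitectureConfig()
    ltrs = [l for l in ltr_features if _is_ltr7(l)]
    # candidate (gap, run_idx, ltr_idx, side) assignments
    candidates: list[tuple[float, int, int, str]] = []
    for li, ltr in enumerate(ltrs):
        for ri, run in enumerate(int_runs):
            if ltr.interval.chrom != run.interval.chrom:
                continue
            if ltr.interval.strand != run.interval.strand:
                continue
            up_gap = run.interval.start - ltr.interval.end
            down_gap = ltr.interval.start - run.interval.end
            if 0 <= up_gap <= config.flank_max_gap:
                candidates.append((up_gap, ri, li, "5"))
            elif 0 <= down_gap <= config.flank_max_gap:
                candidates.append((down_gap, ri, li, "3"))
    candidates.sort(key=lambda c: (c[0], int_runs[c[1]].interval.start, c[2]))
    ltr_taken: set[int] = set()
    side_filled: dict[tuple[int, str], int] = {}
    for gap, ri, li, side in candidates:
        if li in ltr_taken or (ri, side) in side_filled:
            continue
        ltr_taken.add(li)
        side_filled[(ri, side)] = li
    calls: list[ProvirusCall] = []
    for ri, run in enumerate(int_runs):
        if not _long_enough(run, config):
            continue
        li5 = side_filled.get((ri, "5"))
        li3 = side_filled.get((ri, "3"))
        if li5 is None or li3 is None:
            continue
        calls.append(ProvirusCall(run, ltrs[li5], ltrs[li3]))
    calls.sort(key=lambda c: (c.int_run.interval.chrom, c.ltr5.interval.start))
    return calls


def _length_in_window(length: int, config: ArchitectureConfig) -> bool:
    if config.strict_bounds:
        return config.ltr_len_min < length < config.ltr_len_max
    return config.ltr_len_min <= length <= config.ltr_len_max


def call_solitary(ltr_features: Sequence[RepeatFeature],
                  int_features: Sequence[RepeatFeature],
                  config: ArchitectureConfig | None = None,
                  exclude: Iterable[RepeatFeature] = (),
                  ) -> list[SolitaryLtrCall]:
    """Identify solitary LTR7-group elements.

    A call requires an LTR7-group feature with length strictly inside the
    (435, 465) bp window and no HERV-H-int feature within
    ``solitary_window`` bp on either side (strand-agnostic: any nearby
    internal fragment disqualifies). ``exclude`` removes features already
    consumed as provirus flanks.
    """
    config = config or ArchitectureConfig()
    excluded = set(map(id, exclude))
    ints = [r.interval for r in int_features if r.rep_name == INT_NAME]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ints:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    calls: list[SolitaryLtrCall] = []
    for ltr in ltr_features:
        if not _is_ltr7(ltr) or id(ltr) in excluded:
            continue
        if not _length_in_window(ltr.interval.length, config):
            continue
        gap = intervals.nearest_distance(
            ltr.interval, by_chrom.get(ltr.interval.chrom, []))
        if gap > config.solitary_window:
            calls.append(SolitaryLtrCall(ltr, ltr.rep_name, gap))
    calls.sort(key=lambda c: (c.ltr.interval.chrom, c.ltr.interval.start))
    return calls


def classify_annotation(repeats: Sequence[RepeatFeature],
                        config: ArchitectureConfig | None = None,
                        ) -> tuple[list[ProvirusCall], list[SolitaryLtrCall],
                                   list[IntRun]]:
    """Run the full architecture classification on raw repeat annotation."""
    config = config or ArchitectureConfig()
    runs = build_int_runs(repeats, config)
    ltrs = [r for r in repeats if _is_ltr7(r)]
    proviruses = call_full_length(runs, ltrs, config)
    flanks = [l for p in proviruses for l in (p.ltr5, p.ltr3)]
    solitary = call_solitary(ltrs, repeats, config, exclude=flanks)
    return proviruses, solitary, runs


def tally_architecture(provirus_calls: Sequence[ProvirusCall],
                       solitary_calls: Sequence[SolitaryLtrCall]) -> dict:
    """Counts by category, solitary subfamily, and chromosome."""
    sol_sub = Counter(c.subfamily for c in solitary_calls)
    prov_chrom = Counter(c.int_run.interval.chrom for c in provirus_calls)
    sol_chrom = Counter(c.ltr.interval.chrom for c in solitary_calls)
    return {
        "full_length": len(provirus_calls),
        "solitary": len(solitary_calls),
        "solitary_by_subfamily": dict(sorted(sol_sub.items())),
        "full_length_by_chromosome": dict(sorted(prov_chrom.items())),
        "solitary_by_chromosome": dict(sorted(sol_chrom.items())),
    }


def comparison_table(provirus_calls: Sequence[ProvirusCall],
                     solitary_calls: Sequence[SolitaryLtrCall],
                     reference: Mapping | None = None):
    """Observed-vs-reference count table (a report, not an assertion).

    Compares this run's tallies against genome-wide reference counts
    (default: the GRCh38 rmsk reference in :data:`REFERENCE_HG38_COUNTS`).
    Returns a pandas DataFrame with columns category/observed/reference.
    """
    import pandas as pd

    reference = dict(reference or REFERENCE_HG38_COUNTS)
    tally = tally_architecture(provirus_calls, solitary_calls)
    rows = [("full_length", tally["full_length"], reference.get("full_length")),
            ("solitary", tally["solitary"], reference.get("solitary"))]
    ref_sub = reference.get("solitary_by_subfamily", {})
    for sub in LTR7_SUBFAMILIES:
        rows.append((f"solitary:{sub}",
                     tally["solitary_by_subfamily"].get(sub, 0),
                     ref_sub.get(sub)))
    return pd.DataFrame(rows, columns=["category", "observed", "reference"])


def screen_mirna_origin(mdte_calls: Sequence[MdteCall],
                        provirus_calls: Sequence[ProvirusCall],
                        solitary_calls: Sequence[SolitaryLtrCall],
                        config: ArchitectureConfig | None = None,
                        ) -> dict[str, str]:
    """Label each HERV-H MDTE by the architecture of its source element.

    Only calls whose subfamily is HERV-H-int or in the LTR7 group are
    screened. The source repeat is ``full_length`` when it lies inside a
    provirus footprint (flank LTRs included), ``solitary_ltr`` when it is
    a solitary call's LTR, and ``truncated_element`` otherwise — e.g. a
    mature miRNA inside a 63 bp LTR7C fragment far below the consensus
    length.
    """
    spans = [p.span for p in provirus_calls]
    solitary_ivs = [c.ltr.interval for c in solitary_calls]
    labels: dict[str, str] = {}
    for call in mdte_calls:
        if call.subfamily != INT_NAME and not _pattern_matches(
                "LTR7*", call.subfamily):
            continue
        src = call.repeat.interval
        if any(intervals.overlap_bp(src, s) == src.length for s in spans):
            labels[call.mirna.mirna_id] = "full_length"
        elif any(intervals.overlap_bp(src, iv) == src.length
                 for iv in solitary_ivs):
            labels[call.mirna.mirna_id] = "solitary_ltr"
        else:
            labels[call.mirna.mirna_id] = "truncated_element"
    return labels
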