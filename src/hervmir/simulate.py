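"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structures the pipeline classifies, at the
study's design points:

* repeat annotation with planted full-length proviruses (LTR7 flank,
  fragmented >7 kb HERV-H-int run, LTR7 flank), solitary LTRs in the
  (436, 464) bp window, truncated fragments (including the 63 bp LTR7C
  case), and decoys built to fail exactly one rule (near-int LTRs,
  off-window lengths, non-HERV families);
* mature miRNAs planted inside chosen repeats or in repeat-free gaps;
* two-group log2-scale expression matrices (default 16 cases vs 9
  controls) with planted down-regulated genes;
* miRNA/UTR sequence pairs with seed sites planted at known offsets;
* Ct tables realizing a chosen true fold change.

Every generator is a pure function of its parameters plus an explicit
seed; the returned truth manifest fully determines the expected output of
the corresponding pipeline stage.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomicInterval, MirnaFeature, RepeatFeature
from .duplex import normalize_rna, revcomp_rna, _RNA_COMPLEMENT
from .relquant import CtRecord
from .triage import ExpressionMatrix

PLACEMENT_RETRIES = 10_000

#: Minimum clearance between independently placed feature blocks (bp).
#: Larger than both the int-run merge gap (1000) and the solitary-LTR
#: isolation window (200), so independently planted elements never
#: interact under the default architecture thresholds.
BLOCK_BUFFER = 1200


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth manifest of a synthetic data bundle."""

    seed: int
    chrom: str = "chr1"
    proviruses: list = dataclasses.field(default_factory=list)
    solitary: list = dataclasses.field(default_factory=list)
    truncated: list = dataclasses.field(default_factory=list)
    decoys: list = dataclasses.field(default_factory=list)
    mdtes: list = dataclasses.field(default_factory=list)
    outside_mirnas: list = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)
        return path


class _Placer:
    """Rejection-sampling placement of non-overlapping blocks."""

    def __init__(self, rng: np.random.Generator, genome_len: int,
                 buffer: int = BLOCK_BUFFER):
        self.rng = rng
        self.genome_len = genome_len
        self.buffer = buffer
        self.occupied: list[tuple[int, int]] = []

    def place(self, block_len: int) -> int:
        if block_len >= self.genome_len:
            raise RuntimeError(
                f"genome ({self.genome_len} bp) too small for a "
                f"{block_len} bp block")
        for _ in range(PLACEMENT_RETRIES):
            start = int(self.rng.integers(0, self.genome_len - block_len))
            end = start + block_len
            if all(start - self.buffer >= oe or end + self.buffer <= os
                   for os, oe in self.occupied):
                self.occupied.append((start, end))
                return start
        raise RuntimeError(
            f"could not place a {block_len} bp block after "
            f"{PLACEMENT_RETRIES} attempts; genome too crowded")


def _split_int(rng: np.random.Generator, total: int, n_frag: int,
               min_frag: int = 500) -> list[int]:
    if n_frag == 1:
        return [total]
    # partition by randomized proportions, flooring each fragment at min_frag
    props = rng.dirichlet(np.ones(n_frag))
    lens = np.maximum((props * total).astype(int), min_frag)
    lens[-1] = total - int(lens[:-1].sum())
    if lens[-1] < min_frag:  # rebalance from the largest fragment
        deficit = min_frag - int(lens[-1])
        lens[int(np.argmax(lens[:-1]))] -= deficit
        lens[-1] = min_frag
    return [int(x) for x in lens]


def simulate_repeat_annotation(
        n_provirus: int = 5,
        n_solitary: int | Mapping[str, int] = 20,
        n_truncated: int = 10,
        n_decoy: int = 10,
        genome_len: int = 5_000_000,
        seed: int = 0,
        chrom: str = "chr1",
) -> tuple[list[RepeatFeature], SyntheticTruth]:
    """Repeat annotation with planted architecture and decoys.

    ``n_solitary`` may be a total (subfamilies drawn uniformly from the
    LTR7 group) or a mapping subfamily -> count. Decoys cycle through
    four kinds: an in-window LTR7 with a HERV-H-int fragment 50-150 bp
    away, an isolated LTR7 with off-window length, an ERVL-MaLR element
    and a Gypsy element. Truncated elements alternate between short lone
    HERV-H-int fragments and 63 bp LTR7C scraps.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, chrom=chrom)
    placer = _Placer(rng, genome_len)
    features: list[RepeatFeature] = []

    def add(start: int, length: int, name: str, cls: str, fam: str,
            strand: str) -> RepeatFeature:
        f = RepeatFeature(GenomicInterval(chrom, start, start + length, strand),
                          name, cls, fam)
        features.append(f)
        return f

    for _ in range(n_provirus):
        strand = str(rng.choice(["+", "-"]))
        l5 = int(rng.integers(440, 461))
        l3 = int(rng.integers(440, 461))
        g5 = int(rng.integers(0, 151))
        g3 = int(rng.integers(0, 151))
        n_frag = int(rng.integers(1, 4))
        total_int = int(rng.integers(7200, 9001))
        frags = _split_int(rng, total_int, n_frag)
        gaps = [int(rng.integers(100, 801)) for _ in range(n_frag - 1)]
        block_len = l5 + g5 + total_int + sum(gaps) + g3 + l3
        b = placer.place(block_len)
        ltr5 = add(b, l5, "LTR7", "LTR", "ERV1", strand)
        pos = b + l5 + g5
        frag_spans = []
        for fi, flen in enumerate(frags):
            add(pos, flen, "HERV-H-int", "LTR", "ERV1", strand)
            frag_spans.append((pos, pos + flen))
            pos += flen + (gaps[fi] if fi < len(gaps) else 0)
        ltr3 = add(pos + g3, l3, "LTR7", "LTR", "ERV1", strand)
        truth.proviruses.append({
            "strand": strand,
            "ltr5": [ltr5.interval.start, ltr5.interval.end],
            "ltr3": [ltr3.interval.start, ltr3.interval.end],
            "int_span": [frag_spans[0][0], frag_spans[-1][1]],
            "int_fragments": [list(s) for s in frag_spans],
            "int_sum": total_int,
        })

    if isinstance(n_solitary, Mapping):
        sol_plan = [sub for sub, cnt in sorted(n_solitary.items())
                    for _ in range(cnt)]
    else:
        sol_plan = [str(rng.choice(["LTR7", "LTR7B", "LTR7C", "LTR7Y"]))
                    for _ in range(n_solitary)]
    for sub in sol_plan:
        length = int(rng.integers(437, 464))
        strand = str(rng.choice(["+", "-"]))
        b = placer.place(length)
        f = add(b, length, sub, "LTR", "ERV1", strand)
        truth.solitary.append({"subfamily": sub,
                               "span": [f.interval.start, f.interval.end]})

    for i in range(n_truncated):
        strand = str(rng.choice(["+", "-"]))
        if i % 2 == 0:
            length = int(rng.integers(800, 4001))
            b = placer.place(length)
            f = add(b, length, "HERV-H-int", "LTR", "ERV1", strand)
            kind = "short_int"
        else:
            length = 63
            b = placer.place(length)
            f = add(b, length, "LTR7C", "LTR", "ERV1", strand)
            kind = "ltr7c_63bp"
        truth.truncated.append({"kind": kind,
                                "span": [f.interval.start, f.interval.end]})

    decoy_kinds = ("near_int_ltr", "offwindow_ltr", "ervl_malr", "gypsy")
    for i in range(n_decoy):
        kind = decoy_kinds[i % len(decoy_kinds)]
        strand = str(rng.choice(["+", "-"]))
        if kind == "near_int_ltr":
            int_len = int(rng.integers(1000, 3001))
            gap = int(rng.integers(50, 151))
            ltr_len = int(rng.integers(440, 461))
            b = placer.place(int_len + gap + ltr_len)
            add(b, int_len, "HERV-H-int", "LTR", "ERV1", strand)
            f = add(b + int_len + gap, ltr_len, "LTR7", "LTR", "ERV1", strand)
        elif kind == "offwindow_ltr":
            length = int(rng.integers(380, 431)) if rng.random() < 0.5 \
                else int(rng.integers(470, 531))
            b = placer.place(length)
            f = add(b, length, "LTR7", "LTR", "ERV1", strand)
        elif kind == "ervl_malr":
            b = placer.place(350)
            f = add(b, 350, "THE1B", "LTR", "ERVL-MaLR", strand)
        else:
            b = placer.place(500)
            f = add(b, 500, "MamGyp-int", "LTR", "Gypsy", strand)
        truth.decoys.append({"kind": kind,
                             "span": [f.interval.start, f.interval.end]})

    features.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return features, truth


def simulate_mirna_annotation(repeats: Sequence[RepeatFeature],
                              truth: SyntheticTruth,
                              n_in_te: int = 10,
                              n_outside: int = 5,
                              seed: int = 0) -> list[MirnaFeature]:
    """Mature miRNAs planted fully inside repeats or in repeat-free gaps.

    Planted-in-repeat miRNAs are recorded in ``truth.mdtes`` with the
    host's family/subfamily; outside miRNAs land at least 50 bp clear of
    every repeat and must produce no call.
    """
    rng = np.random.default_rng(seed)
    mirnas: list[MirnaFeature] = []
    hosts = [i for i, r in enumerate(repeats) if r.interval.length >= 30]
    if n_in_te > 0 and not hosts:
        raise RuntimeError("no repeat long enough to host a mature miRNA")
    if n_in_te > 0:
        chosen = rng.choice(hosts, size=n_in_te,
                            replace=len(hosts) < n_in_te)
        for k, hi in enumerate(chosen):
            host = repeats[int(hi)]
            length = int(rng.integers(18, 24))
            start = int(rng.integers(host.interval.start,
                                     host.interval.end - length + 1))
            name = f"syn-mir-{k:03d}"
            mirnas.append(MirnaFeature(
                GenomicInterval(host.interval.chrom, start, start + length,
                                host.interval.strand), name))
            truth.mdtes.append({
                "mirna_id": name, "family": host.rep_family,
                "subfamily": host.rep_name,
                "host_span": [host.interval.start, host.interval.end],
            })
    if n_outside > 0:
        margin = 50
        occupied = sorted((r.interval.start, r.interval.end) for r in repeats)
        gaps: list[tuple[int, int]] = []
        prev = 0
        genome_end = (max(e for _, e in occupied) + 100_000) if occupied \
            else 1_000_000
        for s, e in occupied + [(genome_end, genome_end)]:
            if s - prev > 2 * margin + 30:
                gaps.append((prev + margin, s - margin))
            prev = max(prev, e)
        if not gaps:
            raise RuntimeError("no repeat-free gap for outside miRNAs")
        chrom = repeats[0].interval.chrom if repeats else truth.chrom
        for k in range(n_outside):
            gs, ge = gaps[int(rng.integers(0, len(gaps)))]
            length = int(rng.integers(18, 24))
            start = int(rng.integers(gs, ge - length + 1))
            name = f"syn-mir-out-{k:03d}"
            mirnas.append(MirnaFeature(
                GenomicInterval(chrom, start, start + length, "+"), name))
            truth.outside_mirnas.append(name)
    mirnas.sort(key=lambda m: (m.interval.chrom, m.interval.start,
                               m.mirna_id))
    return mirnas


def simulate_expression(n_genes: int = 2000,
                        n_case: int = 16,
                        n_control: int = 9,
                        n_down: int = 50,
                        effect_log2: float = -2.0,
                        noise_sd: float = 0.25,
                        seed: int = 0,
                        ) -> tuple[ExpressionMatrix, dict]:
    """Two-group log2-scale expression matrix with planted down-genes.

    values = baseline (uniform 4-12 log2 units) + group effect (the first
    ``n_down`` genes get ``effect_log2`` in cases) + Gaussian noise.
    Default group sizes mirror the 16-case / 9-control design.
    """
    if n_down > n_genes:
        raise ValueError("n_down must be <= n_genes")
    if n_down > 0 and effect_log2 >= 0:
        raise ValueError("effect_log2 must be negative for down-genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    down = genes[:n_down]
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    case_cols = [f"case{i + 1:02d}" for i in range(n_case)]
    ctrl_cols = [f"ctrl{i + 1:02d}" for i in range(n_control)]
    effect = np.zeros(n_genes)
    effect[:n_down] = effect_log2
    case_vals = (baseline[:, None] + effect[:, None]
                 + rng.normal(0.0, noise_sd, size=(n_genes, n_case)))
    ctrl_vals = (baseline[:, None]
                 + rng.normal(0.0, noise_sd, size=(n_genes, n_control)))
    values = pd.DataFrame(np.hstack([case_vals, ctrl_vals]), index=genes,
                          columns=case_cols + ctrl_cols)
    groups = pd.Series({**{c: "case" for c in case_cols},
                        **{c: "control" for c in ctrl_cols}})
    matrix = ExpressionMatrix(values, groups)
    truth = {"seed": seed, "down_genes": down, "effect_log2": effect_log2,
             "noise_sd": noise_sd}
    return matrix, truth


_SITE_KINDS = ("6mer", "7mer-A1", "7mer-m8", "8mer", "perfect")


def _site_sequence(mirna: str, kind: str) -> str:
    core = revcomp_rna(mirna[1:7])
    m8 = _RNA_COMPLEMENT[mirna[7]]
    if kind == "6mer":
        return core
    if kind == "7mer-A1":
        return core + "A"
    if kind == "7mer-m8":
        return m8 + core
    if kind == "8mer":
        return m8 + core + "A"
    if kind == "perfect":
        return revcomp_rna(mirna)
    raise ValueError(f"unknown site kind {kind!r}")


def _expected_core_start(mirna_len: int, offset: int, kind: str) -> int:
    if kind in ("7mer-m8", "8mer"):
        return offset + 1
    if kind == "perfect":
        return offset + mirna_len - 7
    return offset


def simulate_sequences(utr_len: int = 200,
                       planted_sites: Sequence[tuple[int, str]] = ((50, "8mer"),),
                       seed: int = 0,
                       mirna_len: int = 22,
                       ) -> tuple[str, str, dict]:
    """A random miRNA and a UTR carrying seed sites at known offsets.

    ``planted_sites`` is a list of (offset, kind) with kind one of 6mer /
    7mer-A1 / 7mer-m8 / 8mer / perfect (full reverse complement).
    Overlapping planted sites are a fatal error. Accidental extra seed
    cores arising in the random background are mutated away when they do
    not touch a planted site, so the seed-site scan of the result is
    exactly the planted truth (any unresolvable extras are listed in the
    manifest).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    mirna = "".join(rng.choice(bases, size=mirna_len))
    spans = []
    for offset, kind in planted_sites:
        if kind not in _SITE_KINDS:
            raise ValueError(f"unknown site kind {kind!r}")
        site = _site_sequence(mirna, kind)
        if offset < 0 or offset + len(site) > utr_len:
            raise ValueError(f"site at {offset} ({kind}) exceeds the UTR")
        spans.append((offset, offset + len(site), site))
    spans.sort()
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted sites collide")
    utr = list(rng.choice(bases, size=utr_len))
    for s, e, site in spans:
        utr[s:e] = list(site)
    core = revcomp_rna(mirna[1:7])
    expected = {_expected_core_start(mirna_len, off, kind)
                for off, kind in planted_sites}
    extras: list[int] = []
    for _ in range(200):
        text = "".join(utr)
        hit = -1
        i = text.find(core)
        while i != -1:
            inside = any(s <= i and i + 6 <= e for s, e, _ in spans)
            if i not in expected and not inside:
                overlaps = any(i < e and s < i + 6 for s, e, _ in spans)
                if not overlaps:
                    hit = i
                    break
                if i not in extras:
                    extras.append(i)
            i = text.find(core, i + 1)
        if hit == -1:
            break
        choices = [b for b in "ACGU" if b != utr[hit + 2]]
        utr[hit + 2] = str(rng.choice(choices))
    utr_seq = "".join(utr)
    truth = {"seed": seed, "mirna": mirna,
             "planted": [[off, kind] for off, kind in planted_sites],
             "expected_core_starts": sorted(expected),
             "unresolved_extra_cores": extras}
    return mirna, utr_seq, truth


def simulate_ct(true_fold_change: float = 4.0,
                n_reps: int = 3,
                sd: float = 0.1,
                seed: int = 0,
                target_gene: str = "miR-4454",
                reference_gene: str = "U6",
                case_sample: str = "RT-4",
                control_sample: str = "SV-HUC-1",
                base_delta_ct: float = 5.0,
                reference_ct: float = 20.0,
                ) -> tuple[list[CtRecord], dict]:
    """Ct table realizing a chosen case/control fold change.

    The control group's target sits ``base_delta_ct`` cycles above the
    reference; the case target is shifted by -log2(fold change) cycles,
    so the expected 2^-ddCt equals ``true_fold_change`` exactly at
    sd = 0. Replicates default to triplicate.
    """
    if n_reps < 3:
        raise ValueError("n_reps must be >= 3 (triplicate design)")
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    rng = np.random.default_rng(seed)
    shift = -math.log2(true_fold_change)
    records: list[CtRecord] = []
    for group, sample, delta in (("control", control_sample, base_delta_ct),
                                 ("case", case_sample, base_delta_ct + shift)):
        for rep in range(1, n_reps + 1):
            ref = reference_ct + float(rng.normal(0.0, sd)) if sd > 0 \
                else reference_ct
            tgt = ref + delta + (float(rng.normal(0.0, sd)) if sd > 0 else 0.0)
            records.append(CtRecord(sample, group, reference_gene, ref, rep))
            records.append(CtRecord(sample, group, target_gene, tgt, rep))
    truth = {"seed": seed, "true_fold_change": true_fold_change,
             "base_delta_ct": base_delta_ct, "sd": sd}
    return records, truth
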