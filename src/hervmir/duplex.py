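"""Seed-site enumeration and miRNA:target duplex scoring.

``find_seed_sites`` enumerates canonical miRNA target sites in a 3' UTR:
every occurrence of the Watson-Crick reverse complement of miRNA
nucleotides 2-7 (the 6mer core), upgraded to 7mer-m8 (match to miRNA
position 8), 7mer-A1 (adenosine opposite position 1) or 8mer (both) per
the standard definitions. G·U wobbles do not count in seed matching.

``hybridize`` scores the intermolecular duplex between a miRNA and a
short target window with a nearest-neighbor-style dynamic program: helix
stacks draw on an embedded published Watson-Crick stack table (dG37,
kcal/mol); G·U wobble stacks use a single default value; bulges and
internal loops pay affine penalties and are bounded in size. Scores are
reported as model scores on a kcal/mol scale (lower = more stable); no
claim is made of reproducing any particular web server's energies.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, NamedTuple, Sequence

RNA_ALPHABET = frozenset("ACGU")

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})


def normalize_rna(seq: str) -> str:
    """Uppercase, DNA T accepted and mapped to U; other letters rejected."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def _reverse_pair(pair: str) -> str:
    return pair[1] + pair[0]


def _wc_stack_table() -> dict[tuple[str, str], float]:
    """Published Watson-Crick nearest-neighbor dG37 stacks (kcal/mol).

    Key ``(p1, p2)``: helix step with pair p1 = (miRNA base, target base)
    followed 3'-ward on the miRNA by pair p2. The ten measured parameters
    are completed by the helix-reversal symmetry
    ``(p1, p2) == (rev p2, rev p1)``.
    """
    measured = {
        ("AU", "AU"): -0.93,
        ("AU", "UA"): -1.10,
        ("UA", "AU"): -1.33,
        ("CG", "UA"): -2.08,
        ("CG", "AU"): -2.11,
        ("GC", "UA"): -2.24,
        ("GC", "AU"): -2.35,
        ("CG", "GC"): -2.36,
        ("GC", "GC"): -3.26,
        ("GC", "CG"): -3.42,
    }
    table = dict(measured)
    for p1 in WC_PAIRS:
        for p2 in WC_PAIRS:
            key = (p1, p2)
            if key not in table:
                table[key] = measured[(_reverse_pair(p2), _reverse_pair(p1))]
    return table


#: Default score for any helix step involving a G·U wobble pair.
DEFAULT_WOBBLE_STACK = -1.0


def default_stack_table(wobble: float = DEFAULT_WOBBLE_STACK
                        ) -> dict[tuple[str, str], float]:
    table = _wc_stack_table()
    pairs = WC_PAIRS | WOBBLE_PAIRS
    for p1 in pairs:
        for p2 in pairs:
            if (p1, p2) not in table:
                table[(p1, p2)] = wobble
    return table


@dataclasses.dataclass(frozen=True)
class DuplexScoringModel:
    """Scoring terms of the duplex dynamic program.

    Stack entries are kcal/mol-scaled and negative-favorable; bulge and
    internal-loop penalties are affine (open plus extend per additional
    unpaired base) and non-negative; ``max_bulge`` bounds the unpaired
    stretch allowed on either strand between consecutive pairs.
    """

    stack_energy: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=default_stack_table)
    gu_allowed: bool = True
    bulge_open: float = 3.8
    bulge_extend: float = 0.5
    loop_open: float = 4.0
    loop_extend: float = 0.5
    max_bulge: int = 4

    def __post_init__(self) -> None:
        for p1, p2 in self.stack_energy:
            if p1 in WC_PAIRS and p2 in WC_PAIRS:
                if self.stack_energy[(p1, p2)] > 0:
                    raise ValueError(f"canonical stack ({p1},{p2}) must be <= 0")
        for field in ("bulge_open", "bulge_extend", "loop_open", "loop_extend"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0")
        if self.max_bulge < 0:
            raise ValueError("max_bulge must be >= 0")

    def can_pair(self, a: str, b: str) -> bool:
        pair = a + b
        return pair in WC_PAIRS or (self.gu_allowed and pair in WOBBLE_PAIRS)

    def stack(self, p1: str, p2: str) -> float:
        return self.stack_energy[(p1, p2)]

    def gap_cost(self, gap_mirna: int, gap_target: int) -> float:
        """Penalty for unpaired bases between consecutive pairs."""
        if gap_mirna == 0 and gap_target == 0:
            raise ValueError("adjacent pairs are a stack, not a gap")
        if gap_target == 0:
            return self.bulge_open + self.bulge_extend * (gap_mirna - 1)
        if gap_mirna == 0:
            return self.bulge_open + self.bulge_extend * (gap_target - 1)
        return self.loop_open + self.loop_extend * (gap_mirna + gap_target - 2)

    def transposed(self) -> "DuplexScoringModel":
        """Model with the stack table read in the opposite helix direction."""
        flipped = {(p2, p1): v for (p1, p2), v in self.stack_energy.items()}
        return dataclasses.replace(self, stack_energy=flipped)


DEFAULT_MODEL = DuplexScoringModel()


# ---------------------------------------------------------------------------
# seed sites
# ---------------------------------------------------------------------------

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


class SeedSite(NamedTuple):
    """A canonical seed-match site in a 3' UTR (0-based positions)."""

    utr_position: int   # start of the full site (includes the m8 base)
    site_type: str      # 6mer / 7mer-A1 / 7mer-m8 / 8mer
    core_start: int     # start of the 6mer core within the UTR

    @property
    def length(self) -> int:
        return _SITE_LEN[self.site_type]


def find_seed_sites(mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """Every seed-complementary site of a miRNA in a UTR, typed.

    The 6mer core is the Watson-Crick reverse complement of miRNA
    positions 2-7; overlapping occurrences are all reported, each with
    its strongest applicable type.
    """
    mirna = normalize_rna(mirna_seq)
    utr = normalize_rna(utr_seq)
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt for seed typing")
    core = revcomp_rna(mirna[1:7])
    m8_match = _RNA_COMPLEMENT[mirna[7]]
    sites: list[SeedSite] = []
    i = utr.find(core)
    while i != -1:
        has_m8 = i > 0 and utr[i - 1] == m8_match
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = i - 1 if has_m8 else i
        sites.append(SeedSite(start, site_type, i))
        i = utr.find(core, i + 1)
    return sites


# ---------------------------------------------------------------------------
# duplex dynamic program
# ---------------------------------------------------------------------------

MAX_DUPLEX_LEN = 60

# tie-break rank of the transition into a pair (stack preferred, then a
# bulge in the miRNA, then a bulge in the target, then an internal loop,
# then opening a fresh helix).
_RANK_STACK, _RANK_BULGE_MIR, _RANK_BULGE_TGT, _RANK_LOOP, _RANK_OPEN = range(5)


@dataclasses.dataclass(frozen=True)
class DuplexResult:
    """Optimal intermolecular pairing of a miRNA with a target window.

    ``pairs`` holds (miRNA index, target index) tuples, miRNA 5'->3'
    ascending (target descending, antiparallel); ``score`` is the summed
    model score (0 for an empty pairing).
    """

    score: float
    pairs: tuple[tuple[int, int], ...]
    mirna_seq: str
    target_seq: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_symbol(self, mi: int, tj: int) -> str:
        pair = self.mirna_seq[mi] + self.target_seq[tj]
        if pair in WC_PAIRS:
            return "|"
        if pair in WOBBLE_PAIRS:
            return ":"
        return " "

    def format(self) -> str:
        """Three-line text block: target 5'->3', pair symbols, miRNA 3'->5'."""
        if not self.pairs:
            return (f"target 5' {self.target_seq} 3'\n"
                    f"          {' ' * len(self.target_seq)}\n"
                    f"miRNA  3' {self.mirna_seq[::-1]} 5'")
        # walk in target-ascending order == miRNA-descending order
        pairs = sorted(self.pairs, key=lambda p: p[1])
        top, mid, bot = [], [], []

        def emit(t_range, m_range_desc):
            ts = list(t_range)
            ms = list(m_range_desc)
            for t in ts:
                top.append(self.target_seq[t])
                mid.append(" ")
                bot.append("-")
            for m in ms:
                top.append("-")
                mid.append(" ")
                bot.append(self.mirna_seq[m])

        prev_t, prev_m = -1, len(self.mirna_seq)
        emit(range(0, pairs[0][1]), range(len(self.mirna_seq) - 1,
                                          pairs[0][0], -1))
        for mi, tj in pairs:
            if prev_t >= 0:
                emit(range(prev_t + 1, tj), range(prev_m - 1, mi, -1))
            top.append(self.target_seq[tj])
            mid.append(self.pair_symbol(mi, tj))
            bot.append(self.mirna_seq[mi])
            prev_t, prev_m = tj, mi
        emit(range(prev_t + 1, len(self.target_seq)), range(prev_m - 1, -1, -1))
        return (f"target 5' {''.join(top)} 3'\n"
                f"          {''.join(mid)}\n"
                f"miRNA  3' {''.join(bot)} 5'")


def hybridize(mirna_seq: str, site_seq: str,
              model: DuplexScoringModel | None = None) -> DuplexResult:
    """Minimum-score intermolecular pairing of a miRNA with a target site.

    Pure duplex: every pair joins one miRNA and one target base,
    antiparallel and non-crossing, with no intra-strand structure.
    Unpaired stretches between consecutive pairs are limited to
    ``model.max_bulge`` bases per strand. The traceback is deterministic:
    ties prefer lower score, then more pairs, then stack over
    miRNA-bulge over target-bulge over loop transitions, then 5'-most
    predecessors.
    """
    model = model or DEFAULT_MODEL
    a = normalize_rna(mirna_seq)
    t = normalize_rna(site_seq)
    if not a or not t:
        raise ValueError("hybridize requires non-empty sequences")
    if len(a) > MAX_DUPLEX_LEN or len(t) > MAX_DUPLEX_LEN:
        raise ValueError(f"sequences must be <= {MAX_DUPLEX_LEN} nt")
    c = t[::-1]  # reversed target: pairs ascend in both coordinates
    n, m = len(a), len(c)
    pairable = [[model.can_pair(a[i], c[j]) for j in range(m)]
                for i in range(n)]
    # state[(i, j)] = (score, -npairs, rank, back) for best structure whose
    # 3'-most miRNA pair is (i, j)
    NEG = None
    score = [[None] * m for _ in range(n)]
    npairs = [[0] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    order_best: tuple | None = None
    best_cell: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m):
            if not pairable[i][j]:
                continue
            cand = (0.0, -1, _RANK_OPEN, 0, 0)
            cand_back = None
            p2 = a[i] + c[j]
            for ip in range(max(0, i - 1 - model.max_bulge), i):
                ga = i - ip - 1
                for jp in range(max(0, j - 1 - model.max_bulge), j):
                    if score[ip][jp] is None:
                        continue
                    gc = j - jp - 1
                    if ga == 0 and gc == 0:
                        p1 = a[ip] + c[jp]
                        cost = model.stack(p1, p2)
                        rank = _RANK_STACK
                    elif gc == 0:
                        cost = model.gap_cost(ga, 0)
                        rank = _RANK_BULGE_MIR
                    elif ga == 0:
                        cost = model.gap_cost(0, gc)
                        rank = _RANK_BULGE_TGT
                    else:
                        cost = model.gap_cost(ga, gc)
                        rank = _RANK_LOOP
                    trial = (score[ip][jp] + cost, -(npairs[ip][jp] + 1),
                             rank, ip, jp)
                    if trial < cand:
                        cand = trial
                        cand_back = (ip, jp)
            score[i][j] = cand[0]
            npairs[i][j] = -cand[1]
            back[(i, j)] = cand_back
            overall = (cand[0], cand[1], i, j)
            if order_best is None or overall < order_best:
                order_best = overall
                best_cell = (i, j)
    if best_cell is None or order_best[0] > 0.0:
        return DuplexResult(0.0, (), a, t)
    # traceback
    pairs_rev: list[tuple[int, int]] = []
    cell: tuple[int, int] | None = best_cell
    while cell is not None:
        i, j = cell
        pairs_rev.append((i, m - 1 - j))  # back to forward target coords
        cell = back[cell]
    pairs = tuple(sorted(pairs_rev))
    return DuplexResult(score[best_cell[0]][best_cell[1]], pairs, a, t)


class SiteHybrid(NamedTuple):
    """A seed site with the duplex result of its surrounding window."""

    site: SeedSite
    window_start: int
    result: DuplexResult


def report_mfe(mirna_seq: str, utr_seq: str,
               model: DuplexScoringModel | None = None,
               window_pad: int = 10) -> list[SiteHybrid]:
    """Duplex scores of every seed-anchored window, best first.

    For each seed site a window of miRNA length plus ``window_pad`` nt
    centered on the 6mer core is cut from the UTR and hybridized against
    the miRNA. Returns site/window/result triples sorted by score
    (ascending, i.e. most stable first); empty when the UTR has no seed
    site.
    """
    model = model or DEFAULT_MODEL
    mirna = normalize_rna(mirna_seq)
    utr = normalize_rna(utr_seq)
    if not utr:
        return []
    sites = find_seed_sites(mirna, utr)
    window_len = min(len(mirna) + window_pad, MAX_DUPLEX_LEN)
    out: list[SiteHybrid] = []
    for site in sites:
        center = site.core_start + 3
        w_start = max(0, center - window_len // 2)
        w_end = min(len(utr), w_start + window_len)
        w_start = max(0, w_end - window_len)
        result = hybridize(mirna, utr[w_start:w_end], model)
        out.append(SiteHybrid(site, w_start, result))
    out.sort(key=lambda sh: (sh.result.score, -sh.result.n_pairs,
                             sh.site.utr_position))
    return out


def write_hybrids_tsv(hybrids: Sequence[SiteHybrid], path: str) -> str:
    """Tabular + three-line-block report mirroring the usual hybrid layout."""
    with open(path, "w") as fh:
        fh.write("utr_position\tsite_type\tscore\tn_pairs\twindow_start\n")
        for sh in hybrids:
            fh.write(f"{sh.site.utr_position}\t{sh.site.site_type}\t"
                     f"{sh.result.score:.2f}\t{sh.result.n_pairs}\t"
                     f"{sh.window_start}\n")
        for sh in hybrids:
            fh.write(f"\n# site @{sh.site.utr_position} ({sh.site.site_type}), "
                     f"model score {sh.result.score:.2f} (kcal/mol-scaled)\n")
            fh.write(sh.result.format() + "\n")
    return path
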