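"""k-mer dot plots and conservation-extent estimates.

A dot plot of an element against its family consensus shows how far along
the consensus the element is still recognisable: exact word (k-mer)
matches merged into maximal diagonal segments. ``conservation_extent``
turns the plot into a single number — the rightmost consensus coordinate
up to which every tiling window is covered by matches at a minimum
fraction — used to judge whether an element retains only a 5' portion of
the consensus (e.g. up to the middle of pol).
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class Match(NamedTuple):
    """A maximal run of identical k-mer seeds on one diagonal.

    ``query_pos``/``subject_pos`` are 0-based starts on the forward
    sequences; for ``strand == "-"`` the query segment matches the
    reverse complement of ``subject[subject_pos:subject_pos+length]``.
    """

    query_pos: int
    subject_pos: int
    length: int
    strand: str = "+"


@dataclasses.dataclass(frozen=True)
class DotplotResult:
    matches: tuple[Match, ...]
    k: int
    query_len: int
    subject_len: int


def _seed_hits(query: str, subject: str, k: int) -> list[tuple[int, int]]:
    """All (query_pos, subject_pos) exact k-mer matches; N never matches."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        word = subject[j:j + k]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    hits: list[tuple[int, int]] = []
    for i in range(len(query) - k + 1):
        word = query[i:i + k]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            hits.append((i, j))
    return hits


def _merge_diagonal(hits: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge seed hits into maximal (query_pos, subject_pos, length) segments."""
    hit_set = set(hits)
    segments = []
    for i, j in sorted(hits):
        if (i - 1, j - 1) in hit_set:
            continue  # not the start of a run
        length = k
        while (i + length - k + 1, j + length - k + 1) in hit_set:
            length += 1
        segments.append((i, j, length))
    return segments


def kmer_dotplot(query: str, subject: str, k: int = 11) -> DotplotResult:
    """Exact k-mer dot plot of two DNA sequences, both strands.

    Forward matches are runs of shared k-mers on one diagonal; reverse
    matches compare the query against the reverse complement of the
    subject and are reported in forward-subject coordinates with
    ``strand == "-"``. Sequences shorter than k give an empty plot.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    query = query.upper()
    subject = subject.upper()
    matches: list[Match] = []
    for i, j, length in _merge_diagonal(_seed_hits(query, subject, k), k):
        matches.append(Match(i, j, length, "+"))
    rc = revcomp_dna(subject)
    for i, j, length in _merge_diagonal(_seed_hits(query, rc, k), k):
        # position j..j+length on revcomp(subject) maps to forward coords
        matches.append(Match(i, len(subject) - j - length, length, "-"))
    matches.sort()
    return DotplotResult(tuple(matches), k, len(query), len(subject))


def conservation_extent(dotplot: DotplotResult, subject_len: int,
                        window: int = 200, min_coverage: float = 0.5) -> int:
    """Rightmost subject coordinate with sustained windowed match coverage.

    The subject is tiled with ``window``-bp windows; scanning left to
    right, the extent advances to each window's end while the fraction of
    its bases covered by any match segment stays at least
    ``min_coverage``, and stops at the first window that fails. Returns 0
    if the first window already fails.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0.0 < min_coverage <= 1.0):
        raise ValueError("min_coverage must be in (0, 1]")
    covered = np.zeros(subject_len, dtype=bool)
    for m in dotplot.matches:
        lo = max(0, m.subject_pos)
        hi = min(subject_len, m.subject_pos + m.length)
        if hi > lo:
            covered[lo:hi] = True
    extent = 0
    for start in range(0, subject_len, window):
        end = min(start + window, subject_len)
        if covered[start:end].mean() >= min_coverage:
            extent = end
        else:
            break
    return extent


def plot_dotplot(result: DotplotResult, path: str,
                 title: str | None = None) -> str:
    """Render the dot plot to an image file (forward black, reverse red)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for m in result.matches:
        xs = (m.subject_pos, m.subject_pos + m.length)
        ys = ((m.query_pos, m.query_pos + m.length) if m.strand == "+"
              else (m.query_pos + m.length, m.query_pos))
        ax.plot(xs, ys, color="black" if m.strand == "+" else "red", lw=1)
    ax.set_xlim(0, result.subject_len)
    ax.set_ylim(0, result.query_len)
    ax.set_xlabel("subject (bp)")
    ax.set_ylabel("query (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_dotplot_tsv(result: DotplotResult, path: str) -> str:
    with open(path, "w") as fh:
        fh.write("query_pos\tsubject_pos\tlength\tstrand\n")
        for m in result.matches:
            fh.write(f"{m.query_pos}\t{m.subject_pos}\t{m.length}\t{m.strand}\n")
    return path
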