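"""Differential-expression filter and three-set target triage.

Candidate miRNA targets are nominated by intersecting three gene sets:
predicted target genes, genes down-regulated in cases (log2 fold change
strictly below a threshold, default -1.1, computed as difference of
group-mean log2 expression), and known tumor-suppressor genes. The triage
report carries all seven Venn regions plus the three-way intersection.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DOWN_THRESHOLD = -1.1

VENN_REGIONS = ("targets_only", "down_only", "ts_only",
                "targets_and_down", "targets_and_ts", "down_and_ts",
                "all_three")


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression with group labels."""

    values: pd.DataFrame            # index: genes, columns: samples
    groups: pd.Series               # sample -> group label

    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        for label in (self.case_label, self.control_label):
            n = int((self.groups.loc[self.values.columns] == label).sum())
            if n < 2:
                raise ValueError(f"need >= 2 samples in group {label!r}, got {n}")

    def samples_in(self, label: str) -> list[str]:
        mask = self.groups.loc[self.values.columns] == label
        return list(self.values.columns[mask.values])

    @classmethod
    def from_tsv(cls, expr_path: str | Path, groups_path: str | Path,
                 case_label: str = "case", control_label: str = "control",
                 ) -> "ExpressionMatrix":
        """Load an expression TSV (genes x samples, first column = gene id)
        and a two-column sample/group TSV."""
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        groups_df = pd.read_csv(groups_path, sep="\t")
        groups = pd.Series(groups_df.iloc[:, 1].values,
                           index=groups_df.iloc[:, 0].astype(str))
        return cls(values, groups, case_label, control_label)

    def to_tsv(self, expr_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t")
        pd.DataFrame({"sample": self.groups.index,
                      "group": self.groups.values}).to_csv(
            groups_path, sep="\t", index=False)


@dataclasses.dataclass(frozen=True)
class DeRecord:
    gene: str
    log2fc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.gene}: non-finite log2fc")


def compute_log2fc(matrix: ExpressionMatrix) -> list[DeRecord]:
    """Per-gene log2 fold change: mean(case) - mean(control).

    Values are assumed already log2-scale, so the fold change is a plain
    difference of group means. Genes missing every value in either group
    are dropped with a warning.
    """
    case = matrix.values[matrix.samples_in(matrix.case_label)]
    control = matrix.values[matrix.samples_in(matrix.control_label)]
    case_mean = case.mean(axis=1, skipna=True)
    control_mean = control.mean(axis=1, skipna=True)
    records: list[DeRecord] = []
    for gene in matrix.values.index:
        fc = case_mean[gene] - control_mean[gene]
        if not np.isfinite(fc):
            logger.warning("gene %s dropped: whole-group missing values", gene)
            continue
        records.append(DeRecord(str(gene), float(fc)))
    return records


def filter_down(records: Iterable[DeRecord],
                threshold: float = DEFAULT_DOWN_THRESHOLD) -> set[str]:
    """Genes with log2 fold change strictly below ``threshold``."""
    return {r.gene for r in records if r.log2fc < threshold}


@dataclasses.dataclass(frozen=True)
class TriageReport:
    """Venn decomposition of targets / down-regulated / tumor-suppressor sets."""

    set_targets: frozenset[str]
    set_down: frozenset[str]
    set_ts: frozenset[str]
    venn_counts: Mapping[str, int]
    intersection: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "n_targets": len(self.set_targets),
            "n_down": len(self.set_down),
            "n_ts": len(self.set_ts),
            "venn_counts": dict(self.venn_counts),
            "intersection": list(self.intersection),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [(region, self.venn_counts[region]) for region in VENN_REGIONS]
        return pd.DataFrame(rows, columns=["region", "count"])


def triage(targets: Iterable[str], down: Iterable[str],
           ts: Iterable[str]) -> TriageReport:
    """Three-set Venn decomposition and intersection.

    Inputs are coerced to sets (duplicates ignored); the intersection is
    returned in sorted order. The seven region counts sum to the size of
    the union.
    """
    t, d, s = frozenset(targets), frozenset(down), frozenset(ts)
    counts = {
        "targets_only": len(t - d - s),
        "down_only": len(d - t - s),
        "ts_only": len(s - t - d),
        "targets_and_down": len((t & d) - s),
        "targets_and_ts": len((t & s) - d),
        "down_and_ts": len((d & s) - t),
        "all_three": len(t & d & s),
    }
    return TriageReport(t, d, s, counts, tuple(sorted(t & d & s)))


def read_gene_list(path: str | Path) -> set[str]:
    """One gene identifier per line; whitespace stripped, blanks ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if gene and not gene.startswith("#"):
                genes.add(gene)
    return genes
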