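"""Relative qPCR quantification (2^-ddCt) and group comparisons.

Each replicate's target quantification cycle is normalized to the
reference gene measured in the same (sample, replicate): dCt = Ct(target)
- Ct(reference). Replicate ddCt values subtract the control group's mean
dCt, and relative expression is 2^-ddCt, so the control group's own mean
dCt maps to a fold change of exactly 1. Group summaries report mean +/- SD
of the replicate fold changes; the two-group comparison uses the pooled
Student t-test on dCt, three or more groups a one-way ANOVA.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

CT_MIN, CT_MAX = 0.0, 45.0


@dataclasses.dataclass(frozen=True)
class CtRecord:
    """One well: a quantification cycle for (sample, gene, replicate)."""

    sample: str
    group: str
    gene: str
    ct: float
    replicate: int

    def __post_init__(self) -> None:
        if not (CT_MIN < self.ct < CT_MAX):
            raise ValueError(
                f"Ct {self.ct} outside ({CT_MIN}, {CT_MAX}) for "
                f"{self.sample}/{self.gene}/rep{self.replicate}")


def read_ct_tsv(path: str | Path) -> list[CtRecord]:
    """TSV with columns sample, group, gene, ct, replicate."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [CtRecord(str(r.sample), str(r.group), str(r.gene),
                     float(r.ct), int(r.replicate))
            for r in df.itertuples(index=False)]


def write_ct_tsv(records: Sequence[CtRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tgene\tct\treplicate\n")
        for r in sorted(records, key=lambda r: (r.group, r.sample,
                                                r.gene, r.replicate)):
            fh.write(f"{r.sample}\t{r.group}\t{r.gene}\t{r.ct!r}\t"
                     f"{r.replicate}\n")
    return path


@dataclasses.dataclass(frozen=True)
class RelQuantResult:
    """2^-ddCt quantification of one target gene, case vs control."""

    target_gene: str
    reference_gene: str
    case_delta_ct: tuple[float, ...]     # per-replicate dCt, case group
    control_delta_ct: tuple[float, ...]  # per-replicate dCt, control group
    delta_delta_ct: float                # mean case dCt - mean control dCt
    case_fold_changes: tuple[float, ...]
    control_fold_changes: tuple[float, ...]
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    p_value: float

    @property
    def fold_change(self) -> float:
        """Group-level relative expression 2^-(ddCt of group means)."""
        return 2.0 ** (-self.delta_delta_ct)


def _delta_ct(records: Sequence[CtRecord], target: str, reference: str,
              group: str) -> list[float]:
    by_key: dict[tuple[str, int], dict[str, float]] = {}
    for r in records:
        if r.group != group or r.gene not in (target, reference):
            continue
        by_key.setdefault((r.sample, r.replicate), {})[r.gene] = r.ct
    out: list[float] = []
    for key in sorted(by_key):
        cts = by_key[key]
        if target not in cts:
            continue
        if reference not in cts:
            logger.warning("replicate %s dropped: missing reference Ct", key)
            continue
        out.append(cts[target] - cts[reference])
    return out


def ddct(records: Sequence[CtRecord], target_gene: str, reference_gene: str,
         case_label: str, control_label: str,
         per_replicate: bool = True) -> RelQuantResult:
    """2^-ddCt relative quantification of ``target_gene``.

    dCt is formed per replicate by default; ``per_replicate=False``
    averages each sample's replicates before forming dCt. ddCt subtracts
    the control group's mean dCt, so the control mean normalizes to a
    fold change of 1. The p-value is a pooled Student t-test on the dCt
    values of the two groups.
    """
    case_dct = _delta_ct(records, target_gene, reference_gene, case_label)
    ctrl_dct = _delta_ct(records, target_gene, reference_gene, control_label)
    if not per_replicate:
        case_dct = _sample_mean_delta_ct(records, target_gene, reference_gene,
                                         case_label)
        ctrl_dct = _sample_mean_delta_ct(records, target_gene, reference_gene,
                                         control_label)
    if not case_dct or not ctrl_dct:
        raise ValueError("no usable replicates in one of the groups")
    ctrl_mean_dct = float(np.mean(ctrl_dct))
    ddct_value = float(np.mean(case_dct)) - ctrl_mean_dct
    case_fc = tuple(2.0 ** (-(d - ctrl_mean_dct)) for d in case_dct)
    ctrl_fc = tuple(2.0 ** (-(d - ctrl_mean_dct)) for d in ctrl_dct)
    if min(len(case_dct), len(ctrl_dct)) >= 2:
        stat = group_compare(case_dct, ctrl_dct, mode="t_test")
    else:  # a single dCt per group leaves no within-group variance to test
        stat = GroupComparison(math.nan, math.nan, "t_test")
    return RelQuantResult(
        target_gene=target_gene, reference_gene=reference_gene,
        case_delta_ct=tuple(case_dct), control_delta_ct=tuple(ctrl_dct),
        delta_delta_ct=ddct_value,
        case_fold_changes=case_fc, control_fold_changes=ctrl_fc,
        case_mean=float(np.mean(case_fc)),
        case_sd=float(np.std(case_fc, ddof=1)) if len(case_fc) > 1 else 0.0,
        control_mean=float(np.mean(ctrl_fc)),
        control_sd=float(np.std(ctrl_fc, ddof=1)) if len(ctrl_fc) > 1 else 0.0,
        p_value=stat.p_value)


def _sample_mean_delta_ct(records, target, reference, group):
    by_sample: dict[str, dict[str, list[float]]] = {}
    for r in records:
        if r.group != group or r.gene not in (target, reference):
            continue
        by_sample.setdefault(r.sample, {}).setdefault(r.gene, []).append(r.ct)
    out = []
    for sample in sorted(by_sample):
        cts = by_sample[sample]
        if target not in cts:
            continue
        if reference not in cts:
            logger.warning("sample %s dropped: missing reference Ct", sample)
            continue
        out.append(float(np.mean(cts[target]) - np.mean(cts[reference])))
    return out


class GroupComparison(NamedTuple):
    statistic: float
    p_value: float
    mode: str


#: Significance threshold used in reports.
ALPHA = 0.05


def group_compare(*groups: Sequence[float], mode: str = "auto",
                  ) -> GroupComparison:
    """Pooled Student t-test (two groups) or one-way ANOVA (three or more).

    Degenerate input with zero variance in every group and equal means
    returns statistic 0 and p-value 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 values")
    if mode == "auto":
        mode = "t_test" if len(arrays) == 2 else "anova"
    if mode == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test mode requires exactly two groups")
        if all(np.var(g) == 0 for g in arrays) and np.allclose(
                arrays[0].mean(), arrays[1].mean()):
            return GroupComparison(0.0, 1.0, mode)
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
    elif mode == "anova":
        means = [g.mean() for g in arrays]
        if all(np.var(g) == 0 for g in arrays) and np.allclose(
                means, means[0]):
            return GroupComparison(0.0, 1.0, mode)
        stat, p = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return GroupComparison(float(stat), float(p), mode)
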