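"""Differential abundance for one case-vs-control comparison.

Per protein: a two-sided Mann-Whitney U test on the per-sample normalized
intensities (undetected samples entered as 0, so detection state itself
carries rank information), a fold-change ratio of group means over detected
values, and a classification into up / down / unchanged against the
thresholds p <= 0.05 with ratio >= 1.5 (up) or <= 0.67 (down).

A protein detected in only one of the two groups has no numeric ratio; it
carries the sentinel ``ONLY_IN_CASE`` or ``ONLY_IN_CONTROL`` and, when the p
criterion is met, classifies as up or down respectively (the "only in wt"
entries of the downregulated list).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu

from .io import GroupDesign, MasterTable

__all__ = [
    "RatioSentinel",
    "Thresholds",
    "DiffRecord",
    "mann_whitney",
    "group_ratio",
    "classify",
    "differential_abundance",
    "exact_null_size",
]

#: per-group size up to which the exact (enumeration) null is used when the
#: pooled values carry no ties; zeros from missing values create ties and
#: force the corrected normal approximation
EXACT_MAX_N = 8


class RatioSentinel(enum.Enum):
    ONLY_IN_CASE = "only_in_case"
    ONLY_IN_CONTROL = "only_in_control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Thresholds:
    """Significance and fold-change cut-offs for classification."""

    alpha: float = 0.05
    up_cut: float = 1.5
    down_cut: float = 0.67

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha out of range: {self.alpha}")
        if not self.down_cut < 1 < self.up_cut:
            raise ValueError(
                f"require down_cut < 1 < up_cut, got {self.down_cut}, {self.up_cut}"
            )


@dataclass(frozen=True)
class DiffRecord:
    accession: str
    p_value: float
    ratio: float | RatioSentinel
    mean_case: float
    mean_control: float
    n_detected_case: int
    n_detected_control: int
    classification: str  # up / down / unchanged


def mann_whitney(xs, ys, continuity: bool = True) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration when both samples have <= ``EXACT_MAX_N``
    observations and the pooled values are tie-free; otherwise the normal
    approximation with tie correction (and, by default, continuity
    correction).  When the U statistic sits exactly at its null mean the
    two-sided p is 1 by symmetry.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([xs, ys])
    has_ties = np.unique(pooled).size < pooled.size
    exact = not has_ties and xs.size <= EXACT_MAX_N and ys.size <= EXACT_MAX_N
    res = mannwhitneyu(
        xs,
        ys,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=continuity,
    )
    if res.statistic == xs.size * ys.size / 2.0:
        return 1.0
    return float(min(res.pvalue, 1.0))


def group_ratio(case_values, control_values) -> float | RatioSentinel:
    """Fold change: mean of detected case values / mean of detected control
    values, or a one-group-only sentinel."""
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if case.size == 0 and control.size == 0:
        raise ValueError("protein undetected in both groups")
    if control.size == 0:
        return RatioSentinel.ONLY_IN_CASE
    if case.size == 0:
        return RatioSentinel.ONLY_IN_CONTROL
    return float(case.mean() / control.mean())


def classify(p_value: float, ratio, thr: Thresholds = Thresholds()) -> str:
    """Trichotomy: up / down / unchanged under the stated thresholds."""
    if p_value <= thr.alpha:
        if ratio is RatioSentinel.ONLY_IN_CASE:
            return "up"
        if ratio is RatioSentinel.ONLY_IN_CONTROL:
            return "down"
        if ratio >= thr.up_cut:
            return "up"
        if ratio <= thr.down_cut:
            return "down"
    return "unchanged"


def differential_abundance(
    table: MasterTable,
    case: str,
    control: str,
    design: GroupDesign,
    thr: Thresholds = Thresholds(),
    continuity: bool = True,
) -> list[DiffRecord]:
    """One DiffRecord per protein of a normalized, presence-filtered table.

    The rank test runs on all per-sample values of the two groups with
    missing entries entered as 0; the ratio uses detected values only.
    """
    if case == control:
        raise ValueError("case and control groups must differ")
    if not table.normalized:
        raise ValueError("differential_abundance requires a normalized table")
    design.validate_against(table)
    case_cols = list(design.samples(case))
    control_cols = list(design.samples(control))
    records: list[DiffRecord] = []
    case_block = table.data[case_cols].to_numpy(dtype=float)
    control_block = table.data[control_cols].to_numpy(dtype=float)
    for acc, cvals, gvals in zip(table.accessions, case_block, control_block):
        ratio = group_ratio(cvals, gvals)
        p = mann_whitney(
            np.nan_to_num(cvals, nan=0.0),
            np.nan_to_num(gvals, nan=0.0),
            continuity=continuity,
        )
        n_case = int(np.sum(~np.isnan(cvals)))
        n_control = int(np.sum(~np.isnan(gvals)))
        records.append(
            DiffRecord(
                accession=acc,
                p_value=p,
                ratio=ratio,
                mean_case=float(np.nanmean(cvals)) if n_case else 0.0,
                mean_control=float(np.nanmean(gvals)) if n_control else 0.0,
                n_detected_case=n_case,
                n_detected_control=n_control,
                classification=classify(p, ratio, thr),
            )
        )
    return records


def exact_null_size(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Achievable size of the exact two-sided test at nominal level ``alpha``.

    The exact two-sided p-value is discrete, so the true rejection
    probability under the null is the total null mass of rank arrangements
    whose p-value is <= alpha.  Computed by enumerating the null distribution
    of the rank sum over all C(n1+n2, n1) assignments.
    """
    n = n1 + n2
    counts: dict[int, int] = {}
    for comb in combinations(range(1, n + 1), n1):
        s = sum(comb)
        counts[s] = counts.get(s, 0) + 1
    total = math.comb(n, n1)
    sums = sorted(counts)
    cum = np.cumsum([counts[s] for s in sums])
    upper = np.cumsum([counts[s] for s in reversed(sums)])[::-1]
    size = 0.0
    for i, s in enumerate(sums):
        p = min(1.0, 2.0 * min(cum[i], upper[i]) / total)
        if p <= alpha:
            size += counts[s] / total
    return size
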