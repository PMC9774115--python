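"""Observed total analytical error (TEo) decompositions.

Total observed error combines random and systematic error as
TEo(%) = 2·CV% + |bias%|, with the within-run CV at each spike level and
one of three bias sources:

* TEo_SR — spiking-recovery bias (the assay's internal accuracy),
* TEo_RB — range-based inter-laboratory bias: the paired comparison
  samples are sorted by concentration, split into equal-size groups, and
  each group's Bland–Altman percent bias applies to the spike levels
  falling in its concentration interval,
* TEo_AB — the single overall Bland–Altman percent bias applied to every
  level.

Bias(%) itself is signed, 100·(target − measured)/target; the absolute
value enters TEo.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_stats import AssayValError
from .method_comparison import PairedMeasurements
from .precision import PrecisionTable
from .recovery import RecoveryTable


class InvalidTargetError(AssayValError):
    """Bias%% needs a strictly positive target mean."""


class AlignmentError(AssayValError):
    """Precision and bias tables do not share the same levels."""


class GroupMappingError(AssayValError):
    """A spike level could not be assigned to a concentration group."""


def bias_percent(target_mean: float, measured_mean: float) -> float:
    """Signed bias, 100·(target − measured)/target.

    Positive when the measurement under-reads the target.
    """
    if target_mean <= 0:
        raise InvalidTargetError(f"target mean must be > 0, got {target_mean}")
    return 100.0 * (target_mean - measured_mean) / target_mean


def observed_total_error(cv_percent: float, bias_percent: float) -> float:
    """TEo(%) = 2·CV% + |bias%|."""
    if cv_percent < 0:
        raise ValueError(f"CV%% must be >= 0, got {cv_percent}")
    return 2.0 * cv_percent + abs(bias_percent)


@dataclass(frozen=True)
class RangeGroup:
    interval: Tuple[float, float]
    sample_ids: Tuple[str, ...]
    percent_bias: float


@dataclass
class RangeGroups:
    """Equal-size concentration groups of the paired comparison samples."""

    groups: List[RangeGroup]

    def group_for(self, concentration: float) -> RangeGroup:
        """Group whose interval contains the concentration; extremes clamp
        to the outer groups, gaps resolve to the nearer interval."""
        if not self.groups:
            raise GroupMappingError("no groups defined")
        if concentration <= self.groups[0].interval[1]:
            return self.groups[0]
        for g in self.groups:
            if g.interval[0] <= concentration <= g.interval[1]:
                return g
        for lo_g, hi_g in zip(self.groups, self.groups[1:]):
            if lo_g.interval[1] < concentration < hi_g.interval[0]:
                mid = (lo_g.interval[1] + hi_g.interval[0]) / 2.0
                return lo_g if concentration <= mid else hi_g
        return self.groups[-1]


def make_range_groups(pairs: PairedMeasurements, n_groups: int = 5) -> RangeGroups:
    """Sort samples by in-house concentration and split into equal-size groups.

    Each group's bias is the mean Bland–Altman percent difference
    100·(lab1 − lab2)/pair-mean over its members.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if pairs.n < n_groups:
        raise ValueError(f"{pairs.n} samples cannot fill {n_groups} groups")
    order = np.argsort(pairs.lab1, kind="stable")
    chunks = np.array_split(order, n_groups)
    groups = []
    for chunk in chunks:
        l1 = pairs.lab1[chunk]
        l2 = pairs.lab2[chunk]
        pct = 100.0 * (l1 - l2) / ((l1 + l2) / 2.0)
        groups.append(
            RangeGroup(
                interval=(float(l1.min()), float(l1.max())),
                sample_ids=tuple(pairs.ids[i] for i in chunk),
                percent_bias=float(pct.mean()),
            )
        )
    return RangeGroups(groups=groups)


@dataclass(frozen=True)
class TeoColumn:
    per_level: Dict[str, float]
    average: float


def _check_alignment(precision: PrecisionTable, labels: "List[str]") -> None:
    prec_labels = [r.label for r in precision.rows]
    if prec_labels != labels:
        raise AlignmentError(
            f"level mismatch: precision {prec_labels} vs bias {labels}"
        )


def teo_sr_table(precision: PrecisionTable, recovery: RecoveryTable) -> TeoColumn:
    """Per-level TEo from within-run CV and spiking-recovery bias."""
    _check_alignment(precision, [r.label for r in recovery.rows])
    per = {
        p.label: observed_total_error(p.within_cv, r.srb)
        for p, r in zip(precision.rows, recovery.rows)
    }
    return TeoColumn(per_level=per, average=float(np.mean(list(per.values()))))


def teo_rb_table(precision: PrecisionTable, groups: RangeGroups) -> TeoColumn:
    """Per-level TEo from within-run CV and the matching group's percent bias."""
    per = {}
    for p in precision.rows:
        g = groups.group_for(p.nominal)
        per[p.label] = observed_total_error(p.within_cv, g.percent_bias)
    return TeoColumn(per_level=per, average=float(np.mean(list(per.values()))))


def teo_ab_table(precision: PrecisionTable, overall_percent_bias: float) -> TeoColumn:
    """Per-level TEo from within-run CV and the single overall percent bias."""
    if not np.isfinite(overall_percent_bias):
        raise ValueError("overall percent bias must be finite")
    per = {
        p.label: observed_total_error(p.within_cv, overall_percent_bias)
        for p in precision.rows
    }
    return TeoColumn(per_level=per, average=float(np.mean(list(per.values()))))


@dataclass(frozen=True)
class TotalErrorRow:
    label: str
    nominal: float
    teo_sr: Optional[float]
    teo_rb: Optional[float]
    teo_ab: Optional[float]


@dataclass
class TotalErrorTable:
    rows: List[TotalErrorRow]
    average_sr: Optional[float]
    average_rb: Optional[float]
    average_ab: Optional[float]
    group_map: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def total_error_table(
    precision: PrecisionTable,
    recovery: Optional[RecoveryTable] = None,
    groups: Optional[RangeGroups] = None,
    overall_percent_bias: Optional[float] = None,
) -> TotalErrorTable:
    """Assemble whichever TEo decompositions the available inputs allow."""
    sr = teo_sr_table(precision, recovery) if recovery is not None else None
    rb = teo_rb_table(precision, groups) if groups is not None else None
    ab = (
        teo_ab_table(precision, overall_percent_bias)
        if overall_percent_bias is not None
        else None
    )
    rows = [
        TotalErrorRow(
            label=p.label,
            nominal=p.nominal,
            teo_sr=sr.per_level[p.label] if sr else None,
            teo_rb=rb.per_level[p.label] if rb else None,
            teo_ab=ab.per_level[p.label] if ab else None,
        )
        for p in precision.rows
    ]
    group_map = (
        {p.label: groups.group_for(p.nominal).interval for p in precision.rows}
        if groups
        else {}
    )
    return TotalErrorTable(
        rows=rows,
        average_sr=sr.average if sr else None,
        average_rb=rb.average if rb else None,
        average_ab=ab.average if ab else None,
        group_map=group_map,
    )
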