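"""Within-run (repeatability) and between-run (reproducibility) imprecision.

A spike panel is a set of concentration levels, each measured as a
replicates-per-day matrix over consecutive days.  Within-run imprecision is
the SD/CV% of a single day's replicates; between-run imprecision is the
SD/CV% of the daily means — the literal per-run averages, not pooled
ANOVA variance components.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core_stats import (
    AssayValError,
    EmptyPanelError,
    Measurement,
    SummaryStats,
    filter_censored,
    summarize,
)


class InsufficientDaysError(AssayValError):
    """Between-run imprecision needs at least two days."""


class QCInvalidError(AssayValError):
    """A quality-control replicate was censored or malformed."""


@dataclass
class SpikeLevel:
    """One spike concentration: label, nominal ng/mL, day-major replicate matrix."""

    label: str
    nominal: float
    days: List[List[Measurement]]

    def day(self, day_number: int) -> List[Measurement]:
        """1-based day accessor."""
        if not 1 <= day_number <= len(self.days):
            raise IndexError(
                f"level {self.label}: day {day_number} not in 1..{len(self.days)}"
            )
        return self.days[day_number - 1]

    @property
    def all_censored(self) -> bool:
        return all(not m.is_quantified for day in self.days for m in day)


@dataclass
class SpikePanel:
    """Spike-recovery study design: ordered levels plus the matrix floor.

    ``matrix_floor`` is the nominal concentration assigned to the analyte-free
    serum matrix (blank) to account for potential endogenous analyte when
    computing recovery; 0.1 ng/mL by default.
    """

    levels: List[SpikeLevel]
    matrix_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.matrix_floor <= 0:
            raise ValueError("matrix_floor must be > 0")
        nominals = [lv.nominal for lv in self.levels]
        if any(b <= a for a, b in zip(nominals, nominals[1:])):
            raise ValueError("nominal concentrations must be strictly increasing")
        for lv in self.levels:
            if len(lv.days) < 1:
                raise ValueError(f"level {lv.label}: needs >= 1 day")
            if any(len(day) < 2 for day in lv.days):
                raise ValueError(f"level {lv.label}: needs >= 2 replicates per day")

    @property
    def n_days(self) -> int:
        return min(len(lv.days) for lv in self.levels)

    def level(self, label: str) -> SpikeLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(label)

    def measurable(self) -> "Tuple[SpikePanel, Dict[str, str]]":
        """Subset to quantifiable spiked levels.

        Excludes the matrix blank (nominal 0) and any level whose
        measurements are entirely censored (e.g. a top spike consistently
        reported above the calibration limit), returning the exclusion
        reasons keyed by level label.
        """
        kept: List[SpikeLevel] = []
        excluded: Dict[str, str] = {}
        for lv in self.levels:
            if lv.nominal == 0:
                excluded[lv.label] = "matrix blank (nominal 0)"
            elif lv.all_censored:
                excluded[lv.label] = "all measurements censored"
            else:
                kept.append(lv)
        return SpikePanel(levels=kept, matrix_floor=self.matrix_floor), excluded


def within_run(panel: SpikePanel, day: int = 1) -> "Dict[str, SummaryStats]":
    """Per-level repeatability statistics from a single day's replicates.

    Day 1 is the canonical within-run day of the study design.  A level
    whose replicates on that day are all censored raises
    :class:`~assayval.core_stats.EmptyPanelError`; subset the panel with
    :meth:`SpikePanel.measurable` first for routine table building.
    """
    out: Dict[str, SummaryStats] = {}
    for lv in panel.levels:
        retained, _ = filter_censored(lv.day(day))
        out[lv.label] = summarize([m.value for m in retained])
    return out


def daily_means(level: SpikeLevel) -> "List[float]":
    """Mean of quantified replicates for each day of one level."""
    means = []
    for day in level.days:
        retained, _ = filter_censored(day)
        means.append(sum(m.value for m in retained) / len(retained))
    return means


def between_run(panel: SpikePanel) -> "Dict[str, SummaryStats]":
    """Per-level reproducibility: SD/CV% of the daily replicate means."""
    if panel.n_days < 2:
        raise InsufficientDaysError(
            f"between-run imprecision needs >= 2 days, panel has {panel.n_days}"
        )
    return {lv.label: summarize(daily_means(lv)) for lv in panel.levels}


@dataclass(frozen=True)
class QCResult:
    passed: bool
    cv_percent: float


def qc_gate(
    qc_triplicates: "Dict[str, Sequence[Measurement]]",
    threshold: float = 10.0,
) -> "Dict[str, QCResult]":
    """Daily quality-control gate: pass iff triplicate CV% < threshold (strict).

    Each QC level must supply exactly three quantified measurements.
    """
    results: Dict[str, QCResult] = {}
    for label, reps in qc_triplicates.items():
        if len(reps) != 3:
            raise QCInvalidError(f"QC level {label}: expected 3 replicates, got {len(reps)}")
        if any(not m.is_quantified for m in reps):
            raise QCInvalidError(f"QC level {label}: censored replicate")
        stats = summarize([m.value for m in reps])
        results[label] = QCResult(passed=stats.cv_percent < threshold, cv_percent=stats.cv_percent)
    return results


@dataclass(frozen=True)
class PrecisionRow:
    label: str
    nominal: float
    measured_mean: float
    within_sd: float
    within_cv: float
    between_sd: float
    between_cv: float


@dataclass
class PrecisionTable:
    """Per-level within/between-run imprecision with column averages.

    Averages are arithmetic means over the included (measurable) levels;
    excluded levels and their reasons are retained for the report.
    """

    rows: List[PrecisionRow]
    average_within_cv: float
    average_between_cv: float
    within_day: int = 1
    excluded: Dict[str, str] = field(default_factory=dict)

    def row(self, label: str) -> PrecisionRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def precision_table(panel: SpikePanel, day: int = 1) -> PrecisionTable:
    """Build the full imprecision table over the panel's measurable levels."""
    sub, excluded = panel.measurable()
    if not sub.levels:
        raise EmptyPanelError("no measurable levels in panel")
    within = within_run(sub, day=day)
    between = between_run(sub)
    rows = []
    for lv in sub.levels:
        w, b = within[lv.label], between[lv.label]
        rows.append(
            PrecisionRow(
                label=lv.label,
                nominal=lv.nominal,
                measured_mean=w.mean,
                within_sd=w.sd,
                within_cv=w.cv_percent,
                between_sd=b.sd,
                between_cv=b.cv_percent,
            )
        )
    return PrecisionTable(
        rows=rows,
        average_within_cv=sum(r.within_cv for r in rows) / len(rows),
        average_between_cv=sum(r.between_cv for r in rows) / len(rows),
        within_day=day,
        excluded=excluded,
    )
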