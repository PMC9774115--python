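"""Descriptive statistics and censored-value handling shared by every stage.

Concentrations are in ng/mL throughout. A measurement outside the assay's
calibrated range is carried as a *censored* value holding the range limit
("<0.2" or ">40" on the instrument printout), never as a numeric estimate,
and censored values are excluded — with a logged count — from every
summary statistic rather than imputed.
"""
from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Default calibrated range of the assay (ng/mL).
LOWER_LIMIT = 0.2
UPPER_LIMIT = 40.0


class AssayValError(Exception):
    """Base class for all toolkit errors."""


class InsufficientReplicatesError(AssayValError):
    """Fewer than two quantified replicates were supplied."""


class UndefinedCVError(AssayValError):
    """CV% is undefined because the mean is not positive."""


class EmptyPanelError(AssayValError):
    """Every measurement in a level or panel is censored."""


class Status(str, enum.Enum):
    """Quantification status of a single measurement."""

    QUANTIFIED = "quantified"
    BELOW_RANGE = "below_range"
    ABOVE_RANGE = "above_range"


@dataclass(frozen=True)
class Measurement:
    """One instrument reading.

    For a censored reading ``value`` holds the censoring limit (e.g. 40.0
    for a ">40" report), not an estimate of the true concentration.
    """

    value: float
    status: Status = Status.QUANTIFIED

    def __post_init__(self) -> None:
        if self.status is Status.QUANTIFIED:
            if not math.isfinite(self.value) or self.value < 0:
                raise ValueError(
                    f"quantified measurement must be finite and >= 0, got {self.value}"
                )

    @property
    def is_quantified(self) -> bool:
        return self.status is Status.QUANTIFIED

    @classmethod
    def from_cell(
        cls,
        cell: "str | float",
        lower: float = LOWER_LIMIT,
        upper: float = UPPER_LIMIT,
    ) -> "Measurement":
        """Parse a CSV cell: a number, or ``"<0.2"`` / ``">40"``."""
        if isinstance(cell, str):
            text = cell.strip()
            if text.startswith("<"):
                return cls(float(text[1:]), Status.BELOW_RANGE)
            if text.startswith(">"):
                return cls(float(text[1:]), Status.ABOVE_RANGE)
            value = float(text)
        else:
            value = float(cell)
        if value < lower:
            return cls(lower, Status.BELOW_RANGE)
        if value > upper:
            return cls(upper, Status.ABOVE_RANGE)
        return cls(value)

    def to_cell(self) -> str:
        if self.status is Status.BELOW_RANGE:
            return f"<{self.value:g}"
        if self.status is Status.ABOVE_RANGE:
            return f">{self.value:g}"
        return repr(float(self.value))


@dataclass(frozen=True)
class SummaryStats:
    """Replicate summary: n, mean, sample SD and CV% (= 100·sd/mean)."""

    n: int
    mean: float
    sd: float
    cv_percent: float


def summarize(values: Iterable[float]) -> SummaryStats:
    """Mean, sample SD (n−1 denominator) and CV% of quantified replicates.

    Imprecision in validation studies is reported as SD and CV%; this is
    the single summary used for within-run, between-run and QC statistics.

    Raises
    ------
    InsufficientReplicatesError
        if fewer than two values are supplied.
    UndefinedCVError
        if the mean is not strictly positive.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite value in replicate set")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean <= 0:
        raise UndefinedCVError(f"CV%% undefined for mean {mean}")
    return SummaryStats(n=int(arr.size), mean=mean, sd=sd, cv_percent=100.0 * sd / mean)


def filter_censored(
    measurements: Sequence[Measurement],
) -> "tuple[list[Measurement], Counter]":
    """Drop censored measurements, returning the retained list and drop counts.

    Mirrors the validation-study convention of excluding, never imputing,
    out-of-range readings (e.g. a spike level consistently reported above
    the upper calibration limit is removed from all downstream tables).

    Raises
    ------
    EmptyPanelError
        if every measurement is censored.
    """
    retained = [m for m in measurements if m.is_quantified]
    dropped: Counter = Counter(
        m.status.value for m in measurements if not m.is_quantified
    )
    if not retained:
        raise EmptyPanelError(
            f"all {len(measurements)} measurements censored: {dict(dropped)}"
        )
    return retained, dropped


def quantified_values(measurements: Sequence[Measurement]) -> "list[float]":
    """Values of the quantified measurements (censored silently dropped)."""
    return [m.value for m in measurements if m.is_quantified]
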