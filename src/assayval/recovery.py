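"""Spike-recovery accuracy: percent recovery and spiking-recovery bias.

Percent recovery at a spiked level is the measured increment over the
matrix floor relative to the nominal spike,
%R = 100·(level_mean − floor)/spike, and the spiking-recovery bias is
SRB = %R − 100 (signed; 0 means perfect recovery).  The matrix floor
(default 0.1 ng/mL) stands in for potential endogenous analyte in the
blank serum pool, whose own reading sits below the quantification limit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

from .core_stats import AssayValError, EmptyPanelError
from .precision import SpikePanel, within_run


class InvalidSpikeError(AssayValError):
    """Spike concentration must be strictly positive."""


def percent_recovery(level_mean: float, matrix_floor: float, spike: float) -> float:
    """%R = 100·(level_mean − matrix_floor)/spike."""
    if spike <= 0:
        raise InvalidSpikeError(f"spike must be > 0, got {spike}")
    if level_mean < 0:
        raise ValueError(f"level mean must be >= 0, got {level_mean}")
    return 100.0 * (level_mean - matrix_floor) / spike


@dataclass(frozen=True)
class RecoveryRow:
    label: str
    nominal: float
    level_mean: float
    percent_recovery: float
    srb: float  # signed, = %R − 100

    @property
    def abs_srb(self) -> float:
        return abs(self.srb)


@dataclass
class RecoveryTable:
    rows: List[RecoveryRow]
    matrix_floor: float
    skipped: Dict[str, str] = field(default_factory=dict)

    def row(self, label: str) -> RecoveryRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def recovery_table(panel: SpikePanel, day: int = 1) -> RecoveryTable:
    """Per-level %R and SRB from day-1 replicate means.

    The matrix blank and fully censored levels (e.g. a top spike reading
    above the calibration limit) are skipped with a logged reason.
    """
    sub, excluded = panel.measurable()
    if not sub.levels:
        raise EmptyPanelError("no measurable levels in panel")
    within = within_run(sub, day=day)
    rows = []
    for lv in sub.levels:
        mean = within[lv.label].mean
        pr = percent_recovery(mean, panel.matrix_floor, lv.nominal)
        rows.append(
            RecoveryRow(
                label=lv.label,
                nominal=lv.nominal,
                level_mean=mean,
                percent_recovery=pr,
                srb=pr - 100.0,
            )
        )
    return RecoveryTable(rows=rows, matrix_floor=panel.matrix_floor, skipped=excluded)
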