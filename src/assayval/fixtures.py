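"""Packaged printed values from the ovine serum progesterone validation study.

These are the published per-level results of the IMMULITE 2000 XPi
progesterone validation in spiked sheep serum — the eight quantifiable
spike levels (0.5–30 ng/mL; the blank read below range and the 40 ng/mL
spike above range, both excluded) with their measured day-1 means,
within/between-run CV%, the printed spiking-recovery bias list, and the
three observed-total-error columns — plus the in-house concentrations of
the 30 study samples used in the inter-laboratory comparison and the
quality-control level means.  They serve as deterministic desk-scale
inputs for reproducing the study's headline numbers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .core_stats import Measurement, Status
from .precision import SpikeLevel, SpikePanel

#: Nominal spiked concentrations of the quantifiable levels (ng/mL).
SPIKED: Tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
#: Day-1 measured means at those levels (ng/mL).
MEASURED: Tuple[float, ...] = (0.8, 1.2, 2.5, 5.0, 11.2, 18.4, 26.7, 37.8)
#: Within-run CV% per level.
WITHIN_CV: Tuple[float, ...] = (7.2, 7.0, 2.2, 6.7, 3.2, 2.2, 2.7, 4.0)
#: Between-run CV% per level.
BETWEEN_CV: Tuple[float, ...] = (8.1, 6.3, 3.7, 4.1, 3.3, 3.7, 2.4, 2.8)
#: Published observed-total-error columns (%).
TEO_SR: Tuple[float, ...] = (52.4, 20.1, 26.5, 14.8, 17.8, 26.2, 38.5, 33.5)
TEO_RB: Tuple[float, ...] = (59.5, 36.7, 26.0, 28.8, 21.3, 19.3, 20.3, 22.9)
TEO_AB: Tuple[float, ...] = (38.9, 38.6, 28.9, 37.8, 30.9, 28.9, 29.9, 32.5)
#: Published column averages (within CV, between CV, TEo SR/RB/AB).
AVERAGES: Dict[str, float] = {
    "within_cv": 4.4,
    "between_cv": 4.3,
    "teo_sr": 28.7,
    "teo_rb": 29.3,
    "teo_ab": 33.3,
}

#: Published absolute spiking-recovery bias list (%), per spiked level.
#: The low-level entries reflect unrounded internal means, so they are not
#: exactly recomputable from the rounded measured means above.
SRB_PRINTED: Tuple[float, ...] = (38.0, 6.0, 22.0, 1.5, 11.0, 22.0, 33.0, 26.0)

#: Matrix floor used for recovery calculations (ng/mL).
MATRIX_FLOOR: float = 0.1

#: In-house concentrations (ng/mL) of the 30 study samples sent for
#: inter-laboratory comparison (seven at 0.22–0.7, thirteen at 0.7–2.5,
#: ten at 2.5–8.1).
INHOUSE_SAMPLES: Tuple[float, ...] = (
    0.28, 0.40, 0.47, 0.51, 0.60, 0.68, 0.70,
    0.85, 0.88, 0.92, 0.95, 1.00, 1.20, 1.30, 1.30, 1.60, 1.70, 2.00, 2.20, 2.40,
    2.60, 2.70, 2.90, 3.20, 3.50, 3.70, 4.10, 5.10, 5.30, 8.10,
)

#: Manufacturer mean concentrations of the three daily QC levels (ng/mL).
QC_MEANS: Dict[str, float] = {"low": 0.64, "medium": 7.5, "high": 20.9}


def table1() -> pd.DataFrame:
    """The published per-level validation table as a DataFrame."""
    return pd.DataFrame(
        {
            "spiked": SPIKED,
            "measured": MEASURED,
            "within_cv": WITHIN_CV,
            "between_cv": BETWEEN_CV,
            "teo_sr": TEO_SR,
            "teo_rb": TEO_RB,
            "teo_ab": TEO_AB,
        }
    )


def reconstruct_panel() -> SpikePanel:
    """Synthetic replicate panel that reproduces the printed moments exactly.

    The study's raw replicate readings were never published, only their
    per-level means and CV%.  This deterministic stand-in places five
    replicates per day so that each level's day-1 mean and within-run CV
    and its five daily means' between-run CV equal the printed values to
    machine precision, letting the full pipeline regenerate the published
    table.  It includes the matrix blank (all below range) and the
    40 ng/mL spike (all above range) so the exclusion logic is exercised.
    """
    # mean-0, sample-SD-1 spread pattern; first entry 0 so day 1 keeps the mean
    base = np.array([0.0, -1.0, -0.5, 0.5, 1.0])
    pattern = base / base.std(ddof=1)
    levels = [
        SpikeLevel(
            label="L1",
            nominal=0.0,
            days=[[Measurement(0.2, Status.BELOW_RANGE)] * 5 for _ in range(5)],
        )
    ]
    for i, (nominal, mean, wcv, bcv) in enumerate(
        zip(SPIKED, MEASURED, WITHIN_CV, BETWEEN_CV)
    ):
        days = []
        for day_mean in mean * (1.0 + bcv / 100.0 * pattern):
            reps = day_mean * (1.0 + wcv / 100.0 * pattern)
            days.append([Measurement(float(v)) for v in reps])
        levels.append(SpikeLevel(label=f"L{i + 2}", nominal=nominal, days=days))
    levels.append(
        SpikeLevel(
            label="L10",
            nominal=40.0,
            days=[[Measurement(40.0, Status.ABOVE_RANGE)] * 5 for _ in range(5)],
        )
    )
    return SpikePanel(levels=levels, matrix_floor=MATRIX_FLOOR)


@dataclass(frozen=True)
class PaperFixture:
    table1: pd.DataFrame
    averages: Dict[str, float]
    srb_printed: Tuple[float, ...]
    inhouse_samples: Tuple[float, ...]
    matrix_floor: float
    qc_means: Dict[str, float]


def paper_fixture() -> PaperFixture:
    """All packaged printed study values in one object."""
    return PaperFixture(
        table1=table1(),
        averages=dict(AVERAGES),
        srb_printed=SRB_PRINTED,
        inhouse_samples=INHOUSE_SAMPLES,
        matrix_floor=MATRIX_FLOOR,
        qc_means=dict(QC_MEANS),
    )
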