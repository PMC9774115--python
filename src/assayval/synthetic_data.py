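"""Synthetic spike panels and paired two-laboratory datasets.

The generators reproduce the statistical structure the analysis stages
assume, so every stage is testable end-to-end without instrument data:

* spike panel — each measurement is
  ``(floor + multiplier·nominal)·(1 + day effect)·(1 + replicate noise)``
  with multiplicative Gaussian noise (constant CV per level, matching the
  roughly level-independent CV% of immunoassay replicates), a shared
  per-level-per-day run effect, and censoring outside the calibrated
  range;
* paired labs — true concentrations drawn log-uniform over the study
  range (dense at the low, clinically relevant end), the in-house value
  with multiplicative noise, and the external value derived through a
  constant-plus-proportional inter-instrument bias.

Identical seeds give byte-identical CSV output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .core_stats import LOWER_LIMIT, UPPER_LIMIT, Measurement, Status
from .method_comparison import PairedMeasurements
from .precision import SpikeLevel, SpikePanel

#: Study design: blank plus nine spikes spanning the calibrated range (ng/mL).
DEFAULT_LEVELS: Tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
#: Within-run CV% profile over those levels (edge levels borrow their neighbour).
DEFAULT_CV_PROFILE: Tuple[float, ...] = (7.2, 7.2, 7.0, 2.2, 6.7, 3.2, 2.2, 2.7, 4.0, 4.0)


@dataclass(frozen=True)
class PanelSpec:
    """Generating parameters of a synthetic spike-recovery panel."""

    nominal_levels: Sequence[float] = DEFAULT_LEVELS
    cv_profile: Sequence[float] = DEFAULT_CV_PROFILE
    recovery_multiplier: float = 1.28
    matrix_floor: float = 0.1
    days: int = 5
    replicates: int = 5
    lower_limit: float = LOWER_LIMIT
    upper_limit: float = UPPER_LIMIT
    day_effect_cv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cv_profile) != len(self.nominal_levels):
            raise ValueError("cv_profile must match nominal_levels in length")
        if any(cv < 0 for cv in self.cv_profile) or self.day_effect_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not 0 < self.lower_limit < self.upper_limit:
            raise ValueError("limits must satisfy 0 < lower < upper")
        if self.days < 1 or self.replicates < 2:
            raise ValueError("need >= 1 day and >= 2 replicates")
        if self.recovery_multiplier <= 0 or self.matrix_floor <= 0:
            raise ValueError("recovery_multiplier and matrix_floor must be > 0")


def make_spike_panel(spec: PanelSpec) -> SpikePanel:
    """Generate a seeded spike panel under the spec's error model."""
    rng = np.random.default_rng(spec.seed)
    levels = []
    for idx, (nominal, cv) in enumerate(zip(spec.nominal_levels, spec.cv_profile)):
        true_level = spec.matrix_floor + spec.recovery_multiplier * nominal
        days = []
        for _ in range(spec.days):
            day_effect = rng.normal(0.0, spec.day_effect_cv / 100.0)
            noise = rng.normal(0.0, cv / 100.0, spec.replicates)
            values = true_level * (1.0 + day_effect) * (1.0 + noise)
            days.append(
                [
                    Measurement.from_cell(v, spec.lower_limit, spec.upper_limit)
                    for v in values
                ]
            )
        levels.append(SpikeLevel(label=f"L{idx + 1}", nominal=nominal, days=days))
    return SpikePanel(levels=levels, matrix_floor=spec.matrix_floor)


@dataclass(frozen=True)
class InterlabSpec:
    """Generating parameters of a paired two-laboratory dataset.

    ``pb_slope``/``pb_intercept`` are the proportional and constant
    inter-instrument biases expressed on the in-house axis:
    lab1 = pb_intercept + pb_slope·lab2 in the noise-free limit, so a
    slope above 1 means the in-house instrument reads high.
    """

    n: int = 39
    conc_range: Tuple[float, float] = (0.22, 30.0)
    pb_slope: float = 1.14
    pb_intercept: float = 0.1
    cv_percent: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.pb_slope <= 0:
            raise ValueError("pb_slope must be > 0")
        if not 0 < self.conc_range[0] < self.conc_range[1]:
            raise ValueError("conc_range must satisfy 0 < low < high")
        if self.cv_percent < 0:
            raise ValueError("cv_percent must be >= 0")


def make_interlab(spec: InterlabSpec) -> PairedMeasurements:
    """Generate seeded paired measurements with the specified lab biases."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.conc_range
    truth = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n))
    sigma = spec.cv_percent / 100.0
    # independent multiplicative noise per lab around the error-free signals;
    # deriving lab2 from the noisy lab1 would correlate the labs' errors and
    # bias the regression-based comparison
    lab1 = truth * (1.0 + rng.normal(0.0, sigma, spec.n))
    lab2 = (truth - spec.pb_intercept) / spec.pb_slope * (
        1.0 + rng.normal(0.0, sigma, spec.n)
    )
    lab1 = np.clip(lab1, 1e-6, None)
    lab2 = np.clip(lab2, 1e-6, None)
    ids = [f"S{i + 1:03d}" for i in range(spec.n)]
    return PairedMeasurements(ids=ids, lab1=lab1, lab2=lab2)
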