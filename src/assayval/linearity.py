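"""Reportable-range (linearity) assessment.

Measured level means are regressed on the nominal spiked concentrations by
ordinary least squares; slope and intercept carry two-sided t-tests against
0 so that a slope CI excluding 1 flags proportional difference and an
intercept CI excluding 0 flags constant bias.  A paired t-test on
(measured − nominal) gives a rough overall deviation-from-identity check.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core_stats import AssayValError
from .precision import SpikePanel, within_run


class SingularDesignError(AssayValError):
    """All x values equal: the regression design is singular."""


class DegenerateTestError(AssayValError):
    """The paired t statistic is undefined (zero-variance, nonzero-mean differences)."""


@dataclass(frozen=True)
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    intercept_p: float
    n: int


class PairedT(NamedTuple):
    t: float
    df: int
    p: float


def ols_fit(x: Sequence[float], y: Sequence[float]) -> LinearityFit:
    """Ordinary least squares of measured (y) on nominal (x).

    Requires at least three points with non-constant x.  ``r_squared`` is
    the squared Pearson correlation; p-values are two-sided t-tests of
    slope ≠ 0 and intercept ≠ 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularDesignError("all x values identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearityFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_p=float(res.pvalues[1]),
        intercept_p=float(res.pvalues[0]),
        n=int(x.size),
    )


def paired_t_deviation(
    nominal: Sequence[float], measured_means: Sequence[float]
) -> PairedT:
    """Paired t-test on the per-level differences (measured − nominal).

    Identical columns are a well-defined no-deviation case (t = 0, p = 1).
    Zero-variance differences with a nonzero mean leave t undefined and
    raise :class:`DegenerateTestError`.
    """
    a = np.asarray(nominal, dtype=float)
    b = np.asarray(measured_means, dtype=float)
    if a.size != b.size:
        raise ValueError("columns must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 paired values")
    d = b - a
    if np.ptp(d) == 0:
        if d[0] == 0:
            return PairedT(t=0.0, df=int(a.size - 1), p=1.0)
        raise DegenerateTestError("constant nonzero differences: t undefined")
    t, p = stats.ttest_rel(b, a)
    return PairedT(t=float(t), df=int(a.size - 1), p=float(p))


@dataclass(frozen=True)
class LinearityReport:
    fit: LinearityFit
    paired_t: PairedT


def assess_linearity(
    panel: SpikePanel, day: int = 1, use_replicates: bool = False
) -> LinearityReport:
    """Linearity of the panel's measurable levels against nominal.

    By default each level contributes its day-1 replicate mean (the study's
    reportable-range design); with ``use_replicates`` every individual
    replicate enters both the regression and the paired t-test, which
    sharpens the deviation test considerably (eight means rarely reach
    significance that forty replicates do).
    """
    sub, _ = panel.measurable()
    within = within_run(sub, day=day)
    nominal = np.array([lv.nominal for lv in sub.levels])
    means = np.array([within[lv.label].mean for lv in sub.levels])
    if use_replicates:
        xs, ys = [], []
        for lv in sub.levels:
            for m in lv.day(day):
                if m.is_quantified:
                    xs.append(lv.nominal)
                    ys.append(m.value)
        fit = ols_fit(xs, ys)
        paired = paired_t_deviation(xs, ys)
    else:
        fit = ols_fit(nominal, means)
        paired = paired_t_deviation(nominal, means)
    return LinearityReport(fit=fit, paired_t=paired)
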