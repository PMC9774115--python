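"""Inter-laboratory agreement analysis.

Two instruments measure the same samples; agreement is characterised by

* Passing–Bablok regression — a nonparametric fit whose slope is the
  offset median of all pairwise slopes, robust to measurement error in
  both axes.  The intercept reflects constant bias and the slope
  proportional bias; either is flagged when its 95% CI excludes 0 / 1.
* a CUSUM test of the linearity assumption underlying the fit,
* Spearman rank correlation with a Fisher-transform CI, and
* Bland–Altman analysis — differences against pair means, with 95% limits
  of agreement mean ± 1.96·SD, a percent-difference variant, and an OLS
  slope of difference on pair mean to quantify proportional error.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core_stats import AssayValError


class InsufficientPairsError(AssayValError):
    """Fewer than three paired measurements."""


class DegenerateDataError(AssayValError):
    """No informative pairwise slope exists (e.g. all x identical)."""


class UndefinedCorrelationError(AssayValError):
    """A constant column leaves rank correlation undefined."""


@dataclass
class PairedMeasurements:
    """Paired two-laboratory measurements; lab1 is the in-house instrument."""

    ids: List[str]
    lab1: np.ndarray
    lab2: np.ndarray

    def __post_init__(self) -> None:
        self.lab1 = np.asarray(self.lab1, dtype=float)
        self.lab2 = np.asarray(self.lab2, dtype=float)
        if not (len(self.ids) == self.lab1.size == self.lab2.size):
            raise ValueError("ids, lab1, lab2 must have equal length")
        if np.any(self.lab1 <= 0) or np.any(self.lab2 <= 0):
            raise ValueError("all paired values must be quantified and > 0")

    @property
    def n(self) -> int:
        return self.lab1.size


@dataclass(frozen=True)
class PassingBablokFit:
    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    intercept_ci: Tuple[float, float]
    n: int
    n_slopes: int

    @property
    def proportional_bias(self) -> bool:
        return not (self.slope_ci[0] <= 1.0 <= self.slope_ci[1])

    @property
    def constant_bias(self) -> bool:
        return not (self.intercept_ci[0] <= 0.0 <= self.intercept_ci[1])


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All informative pairwise slopes S_ij, i < j.

    Ties in both coordinates contribute nothing; tied x with differing y
    contribute signed infinities (they anchor the ordering but can never
    be the median on sane data); slopes exactly −1 are discarded, the
    classical convention that keeps the estimator equivariant under
    swapping the axes.
    """
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    vertical = dx == 0
    slopes = np.empty_like(dy, dtype=float)
    np.divide(dy, dx, out=slopes, where=~vertical)
    slopes[vertical] = np.sign(dy[vertical]) * np.inf
    return slopes[slopes != -1.0]


def passing_bablok(
    x: Sequence[float], y: Sequence[float], z: float = 1.96
) -> PassingBablokFit:
    """Passing–Bablok regression of y on x.

    The slope is the K-offset median of the sorted pairwise slopes, where
    K counts slopes below −1 (this offset makes the estimator consistent
    without assuming which variable carries the error).  The 95% CI uses
    the original rank method: C = z·√(n(n−1)(2n+5)/18) ranks either side
    of the median.  The intercept is median(y − slope·x), with its CI
    evaluated at the slope CI endpoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientPairsError(f"need >= 3 pairs, got {n}")
    slopes = np.sort(_pairwise_slopes(x, y))
    N = slopes.size
    if N == 0 or not np.any(np.isfinite(slopes)):
        raise DegenerateDataError("no finite pairwise slope")
    K = int(np.count_nonzero(slopes < -1.0))

    def offset_median(offset: int) -> float:
        # median of slopes shifted right by `offset` ranks (1-based logic)
        if N % 2 == 1:
            idx = (N - 1) // 2 + offset
            return float(slopes[min(max(idx, 0), N - 1)])
        lo = N // 2 - 1 + offset
        hi = N // 2 + offset
        lo = min(max(lo, 0), N - 1)
        hi = min(max(hi, 0), N - 1)
        return float((slopes[lo] + slopes[hi]) / 2.0)

    b = offset_median(K)
    C = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - C) / 2.0))
    M2 = N - M1 + 1
    lo_idx = min(max(M1 + K, 1), N) - 1
    hi_idx = min(max(M2 + K, 1), N) - 1
    b_lo, b_hi = float(slopes[lo_idx]), float(slopes[hi_idx])

    a = float(np.median(y - b * x))
    a_lo = float(np.median(y - b_hi * x))
    a_hi = float(np.median(y - b_lo * x))
    return PassingBablokFit(
        slope=b,
        slope_ci=(b_lo, b_hi),
        intercept=a,
        intercept_ci=(min(a_lo, a_hi), max(a_lo, a_hi)),
        n=n,
        n_slopes=N,
    )


#: Kolmogorov–Smirnov critical values for the CUSUM linearity statistic.
_KS_CRITICAL = {0.10: 1.22, 0.05: 1.36, 0.025: 1.48, 0.01: 1.63}


@dataclass(frozen=True)
class CusumResult:
    statistic: float
    n_pos: int
    n_neg: int
    p_bound: str
    all_on_line: bool = False

    def rejects_at(self, alpha: float) -> bool:
        if alpha not in _KS_CRITICAL:
            raise ValueError(f"alpha must be one of {sorted(_KS_CRITICAL)}")
        return self.statistic >= _KS_CRITICAL[alpha]


def cusum_path(scores: Sequence[int]) -> np.ndarray:
    """Cumulative sums of ±1/0 residual-side scores in ranked order."""
    return np.cumsum(np.asarray(scores, dtype=float))


def cusum_linearity(
    x: Sequence[float], y: Sequence[float], fit: PassingBablokFit
) -> CusumResult:
    """CUSUM test of the linearity assumption behind a Passing–Bablok fit.

    Each point scores +1/−1 by its side of the fitted line (0 if exactly
    on it); points are ranked by their projection along the fitted line
    and the score path cumulated.  A curved relation produces long
    same-sign runs and a large excursion; max|cusum| normalised by
    √(n⁺·n⁻/(n⁺+n⁻)) is compared against Kolmogorov–Smirnov critical
    values, so the p-value is reported as a tabulated bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - (fit.intercept + fit.slope * x)
    scores = np.sign(resid).astype(int)
    # distance of each point along the fitted line orders the path
    b = fit.slope
    if b != 0 and np.isfinite(b):
        d = (y + x / b) / math.sqrt(1.0 + 1.0 / (b * b))
    else:
        d = x.astype(float)
    order = np.lexsort((x, d))
    path = cusum_path(scores[order])
    n_pos = int(np.count_nonzero(scores > 0))
    n_neg = int(np.count_nonzero(scores < 0))
    max_excursion = float(np.max(np.abs(path))) if path.size else 0.0
    if n_pos == 0 and n_neg == 0:
        return CusumResult(0.0, 0, 0, "p >= 0.10", all_on_line=True)
    if n_pos == 0 or n_neg == 0:
        stat = math.inf if max_excursion > 0 else 0.0
    else:
        stat = max_excursion / math.sqrt(n_pos * n_neg / (n_pos + n_neg))
    if stat < _KS_CRITICAL[0.10]:
        bound = "p >= 0.10"
    elif stat < _KS_CRITICAL[0.05]:
        bound = "0.05 <= p < 0.10"
    elif stat < _KS_CRITICAL[0.025]:
        bound = "0.025 <= p < 0.05"
    elif stat < _KS_CRITICAL[0.01]:
        bound = "0.01 <= p < 0.025"
    else:
        bound = "p < 0.01"
    return CusumResult(stat, n_pos, n_neg, bound)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci: Tuple[float, float]
    p: float
    n: int


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Tie-aware Spearman rank correlation with a Fisher-transform 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientPairsError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant column")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if x.size > 3 and abs(rho) < 1:
        se = math.sqrt(1.06 / (x.size - 3))
        zr = math.atanh(rho)
        ci = (math.tanh(zr - 1.96 * se), math.tanh(zr + 1.96 * se))
    else:
        ci = (rho, rho)
    return SpearmanResult(rho=rho, ci=ci, p=float(p), n=int(x.size))


@dataclass(frozen=True)
class ProportionalError:
    slope: float
    p: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary; differences are lab1 − lab2 (in-house minus external)."""

    n: int
    mean_bias: float
    bias_sd: float
    loa: Tuple[float, float]
    bias_ci: Tuple[float, float]
    mean_percent_bias: float
    percent_bias_sd: float
    percent_loa: Tuple[float, float]
    proportional: ProportionalError
    n_excluded_zero_mean: int = 0


def bland_altman(
    pairs: PairedMeasurements, mode: str = "absolute"
) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of paired two-laboratory data.

    Absolute and percent-difference summaries are always both computed;
    ``mode`` is accepted for interface symmetry with the CLI.  Percent
    differences are 100·(lab1 − lab2)/pair-mean; a zero pair mean (not
    possible for positive concentrations) would exclude the sample with a
    logged count.  Proportional error is the OLS slope of the difference
    on the pair mean with its two-sided p-value.
    """
    if mode not in ("absolute", "percent"):
        raise ValueError(f"mode must be 'absolute' or 'percent', got {mode!r}")
    if pairs.n < 3:
        raise InsufficientPairsError(f"need >= 3 pairs, got {pairs.n}")
    d = pairs.lab1 - pairs.lab2
    m = (pairs.lab1 + pairs.lab2) / 2.0
    mean_bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (mean_bias - 1.96 * sd, mean_bias + 1.96 * sd)
    tcrit = stats.t.ppf(0.975, pairs.n - 1)
    half = tcrit * sd / math.sqrt(pairs.n)
    bias_ci = (mean_bias - half, mean_bias + half)

    nonzero = m != 0
    n_excluded = int(np.count_nonzero(~nonzero))
    pct = 100.0 * d[nonzero] / m[nonzero]
    mean_pct = float(pct.mean())
    pct_sd = float(pct.std(ddof=1))
    pct_loa = (mean_pct - 1.96 * pct_sd, mean_pct + 1.96 * pct_sd)

    if np.ptp(m) == 0:
        prop = ProportionalError(slope=0.0, p=1.0)
    else:
        res = sm.OLS(d, sm.add_constant(m)).fit()
        prop = ProportionalError(slope=float(res.params[1]), p=float(res.pvalues[1]))
    return BlandAltmanResult(
        n=pairs.n,
        mean_bias=mean_bias,
        bias_sd=sd,
        loa=loa,
        bias_ci=bias_ci,
        mean_percent_bias=mean_pct,
        percent_bias_sd=pct_sd,
        percent_loa=pct_loa,
        proportional=prop,
        n_excluded_zero_mean=n_excluded,
    )


@dataclass(frozen=True)
class ComparisonReport:
    pb: PassingBablokFit
    cusum: CusumResult
    spearman: SpearmanResult
    bland_altman: BlandAltmanResult


def compare_labs(
    pairs: PairedMeasurements, direction: str = "lab1_on_lab2"
) -> ComparisonReport:
    """Full inter-laboratory comparison.

    By default the in-house instrument (lab1) is regressed on the external
    reference laboratory (lab2), the method-comparison convention that
    puts the comparator on x; ``direction="lab2_on_lab1"`` swaps the axes.
    Bland–Altman differences are always lab1 − lab2.
    """
    if direction == "lab1_on_lab2":
        x, y = pairs.lab2, pairs.lab1
    elif direction == "lab2_on_lab1":
        x, y = pairs.lab1, pairs.lab2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    pb = passing_bablok(x, y)
    return ComparisonReport(
        pb=pb,
        cusum=cusum_linearity(x, y, pb),
        spearman=spearman(x, y),
        bland_altman=bland_altman(pairs),
    )
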