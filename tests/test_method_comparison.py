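import numpy as np
import pytest

from _oracles import pb_oracle
from assayval.method_comparison import (
    DegenerateDataError,
    InsufficientPairsError,
    PairedMeasurements,
    PassingBablokFit,
    UndefinedCorrelationError,
    bland_altman,
    compare_labs,
    cusum_linearity,
    cusum_path,
    passing_bablok,
    spearman,
)
from assayval.synthetic_data import InterlabSpec, make_interlab


def pairs_from(lab1, lab2):
    return PairedMeasurements(
        ids=[f"s{i}" for i in range(len(lab1))], lab1=lab1, lab2=lab2
    )


class TestPassingBablok:
    def test_identity(self):
        x = [0.5, 1.0, 2.0, 5.0, 10.0]
        fit = passing_bablok(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert not fit.proportional_bias
        assert not fit.constant_bias

    def test_hand_checkable_instance(self):
        fit = passing_bablok([1, 2, 3, 10], [2.1, 3.9, 6.2, 19.8])
        assert fit.slope == pytest.approx(1.9770833, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0760417, abs=1e-6)
        assert fit.n_slopes == 6

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 31))
            x = rng.uniform(0.2, 30, n)
            y = 0.1 + 1.2 * x * (1 + rng.normal(0, 0.08, n))
            fit = passing_bablok(x, y)
            b, a = pb_oracle(list(x), list(y))
            assert fit.slope == pytest.approx(b, rel=1e-12, abs=1e-12)
            assert fit.intercept == pytest.approx(a, rel=1e-12, abs=1e-12)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(1, 20, 15)
        y = 0.5 + 1.3 * x + rng.normal(0, 0.3, 15)
        base = passing_bablok(x, y)
        k = 3.7
        scaled = passing_bablok(k * x, k * y)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.intercept == pytest.approx(k * base.intercept, rel=1e-9, abs=1e-9)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.uniform(1, 20, 21)
        y = 1.4 * x + rng.normal(0, 0.2, 21)
        forward = passing_bablok(x, y).slope
        backward = passing_bablok(y, x).slope
        assert forward * backward == pytest.approx(1.0, abs=0.02)

    def test_ci_orders_and_contains_estimate(self, rng):
        x = rng.uniform(0.5, 25, 40)
        y = 0.2 + 1.1 * x * (1 + rng.normal(0, 0.05, 40))
        fit = passing_bablok(x, y)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]

    def test_errors(self):
        with pytest.raises(InsufficientPairsError):
            passing_bablok([1, 2], [1, 2])
        with pytest.raises(DegenerateDataError):
            passing_bablok([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestCusum:
    def _unit_fit(self, n):
        return PassingBablokFit(
            slope=1.0, slope_ci=(1.0, 1.0), intercept=0.0,
            intercept_ci=(0.0, 0.0), n=n, n_slopes=n * (n - 1) // 2,
        )

    def test_hand_computed_path_and_statistic(self):
        """Four positive then four negative residuals around y = x: the
        cusum path climbs to 4 and H = 4/√2 ≈ 2.83, far past rejection."""
        x = np.arange(1.0, 9.0)
        e = 0.05
        y = x + np.array([e, e, e, e, -e, -e, -e, -e])
        res = cusum_linearity(x, y, self._unit_fit(8))
        assert (res.n_pos, res.n_neg) == (4, 4)
        assert res.statistic == pytest.approx(4 / np.sqrt(2), abs=1e-9)
        assert res.rejects_at(0.01)
        assert res.p_bound == "p < 0.01"

    def test_cusum_path_partial_sums(self):
        assert list(cusum_path([1, 1, -1, 0, -1, 1])) == [1, 2, 1, 1, 0, 1]

    def test_alternating_scatter_not_significant(self):
        x = np.arange(1.0, 41.0)
        y = x + 0.05 * np.tile([1.0, -1.0], 20)
        res = cusum_linearity(x, y, self._unit_fit(40))
        assert not res.rejects_at(0.05)
        assert res.p_bound == "p >= 0.10"

    def test_curvature_rejected(self):
        """A quadratic relation leaves long same-sign runs around any line."""
        x = np.linspace(0.5, 30, 40)
        y = x**2
        fit = passing_bablok(x, y)
        res = cusum_linearity(x, y, fit)
        assert res.rejects_at(0.05)

    def test_all_points_on_line_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = PassingBablokFit(
            slope=2.0, slope_ci=(2.0, 2.0), intercept=0.0,
            intercept_ci=(0.0, 0.0), n=4, n_slopes=6,
        )
        res = cusum_linearity(x, 2 * x, fit)
        assert res.all_on_line
        assert not res.rejects_at(0.05)


class TestSpearman:
    def test_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2.0, 5.0, 7.0, 20.0]).rho == pytest.approx(1.0)
        assert spearman(x, [20.0, 7.0, 5.0, 2.0]).rho == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # Σd² = 4 → rho = 1 − 6·4/(5·24) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.ci[0] < 0.8 < res.ci[1]

    def test_constant_column_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_labs_zero_bias(self):
        p = pairs_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = bland_altman(p)
        assert res.mean_bias == 0
        assert res.loa == (0.0, 0.0)

    def test_hand_computable_triple(self):
        p = pairs_from([10.0, 20.0, 30.0], [8.0, 16.0, 24.0])
        res = bland_altman(p)
        assert res.mean_bias == pytest.approx(4.0)
        assert res.bias_sd == pytest.approx(2.0)
        assert res.loa == pytest.approx((0.08, 7.92))
        assert res.mean_percent_bias == pytest.approx(200 / 9, abs=1e-9)
        assert res.percent_bias_sd == pytest.approx(0.0, abs=1e-9)

    def test_proportional_bias_detected(self, rng):
        """With the external lab reading low by a constant factor, the
        difference grows with the pair mean."""
        lab1 = rng.uniform(0.5, 30, 200)
        lab2 = lab1 / 1.14 * (1 + rng.normal(0, 0.02, 200))
        res = bland_altman(pairs_from(lab1, lab2))
        assert res.mean_bias > 0
        assert res.proportional.slope > 0
        assert res.proportional.p < 1e-6

    def test_loa_cover_95_percent_on_gaussian_differences(self, rng):
        lab2 = rng.uniform(5, 20, 4000)
        lab1 = lab2 + rng.normal(1.0, 0.5, 4000)
        res = bland_altman(pairs_from(lab1, lab2))
        d = lab1 - lab2
        frac = np.mean((d >= res.loa[0]) & (d <= res.loa[1]))
        assert frac == pytest.approx(0.95, abs=0.02)


def test_compare_labs_directions(default_pairs):
    rep = compare_labs(default_pairs)
    swapped = compare_labs(default_pairs, direction="lab2_on_lab1")
    assert rep.pb.slope * swapped.pb.slope == pytest.approx(1.0, abs=0.05)
    assert rep.bland_altman.mean_bias > 0  # in-house reads higher by design
    with pytest.raises(ValueError):
        compare_labs(default_pairs, direction="sideways")


def test_paired_measurements_validation():
    with pytest.raises(ValueError):
        PairedMeasurements(ids=["a"], lab1=[1.0, 2.0], lab2=[1.0, 2.0])
    with pytest.raises(ValueError):
        PairedMeasurements(ids=["a", "b"], lab1=[1.0, 0.0], lab2=[1.0, 2.0])
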