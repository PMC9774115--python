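import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from assayval.method_comparison import PairedMeasurements
from assayval.precision import PrecisionRow, PrecisionTable
from assayval.recovery import RecoveryRow, RecoveryTable
from assayval.total_error import (
    AlignmentError,
    InvalidTargetError,
    RangeGroup,
    RangeGroups,
    bias_percent,
    make_range_groups,
    observed_total_error,
    teo_ab_table,
    teo_rb_table,
    teo_sr_table,
    total_error_table,
)


def make_precision(labels, nominals, within_cvs):
    rows = [
        PrecisionRow(
            label=l, nominal=n, measured_mean=n, within_sd=0.0,
            within_cv=cv, between_sd=0.0, between_cv=cv,
        )
        for l, n, cv in zip(labels, nominals, within_cvs)
    ]
    return PrecisionTable(
        rows=rows,
        average_within_cv=float(np.mean(within_cvs)),
        average_between_cv=float(np.mean(within_cvs)),
    )


def make_recovery(labels, nominals, srbs):
    rows = [
        RecoveryRow(
            label=l, nominal=n, level_mean=n,
            percent_recovery=100 + s, srb=s,
        )
        for l, n, s in zip(labels, nominals, srbs)
    ]
    return RecoveryTable(rows=rows, matrix_floor=0.1)


@pytest.mark.parametrize(
    "target, measured, expected",
    [(10.0, 10.0, 0.0), (10.0, 11.2, -12.0), (20.0, 15.0, 25.0)],
)
def test_bias_percent_hand_cases(target, measured, expected):
    assert bias_percent(target, measured) == pytest.approx(expected)


def test_bias_percent_invalid_target():
    with pytest.raises(InvalidTargetError):
        bias_percent(0.0, 1.0)


@pytest.mark.parametrize(
    "cv, bias, expected",
    [(7.2, 38.0, 52.4), (0.0, 0.0, 0.0), (3.0, -10.0, 16.0)],
)
def test_observed_total_error_hand_cases(cv, bias, expected):
    assert observed_total_error(cv, bias) == pytest.approx(expected)


def test_observed_total_error_negative_cv():
    with pytest.raises(ValueError):
        observed_total_error(-1.0, 5.0)


@given(
    cv=st.floats(0, 20),
    bias=st.floats(-50, 50),
    dcv=st.floats(0, 5),
    dbias=st.floats(0, 5),
)
def test_teo_bounds_and_monotonicity(cv, bias, dcv, dbias):
    teo = observed_total_error(cv, bias)
    assert teo >= 2 * cv
    assert teo >= abs(bias)
    assert observed_total_error(cv + dcv, bias) >= teo
    grown = bias + dbias if bias >= 0 else bias - dbias
    assert observed_total_error(cv, grown) >= teo


def test_teo_sr_composition():
    prec = make_precision(["A", "B"], [1.0, 2.0], [3.0, 4.0])
    rec = make_recovery(["A", "B"], [1.0, 2.0], [10.0, -20.0])
    col = teo_sr_table(prec, rec)
    assert col.per_level == {"A": 16.0, "B": 28.0}
    assert col.average == pytest.approx(22.0)


def test_teo_sr_level_mismatch():
    prec = make_precision(["A", "B"], [1.0, 2.0], [3.0, 4.0])
    rec = make_recovery(["A", "C"], [1.0, 2.0], [0.0, 0.0])
    with pytest.raises(AlignmentError):
        teo_sr_table(prec, rec)


def test_teo_rb_zero_group_bias_reduces_to_2cv():
    prec = make_precision(["A", "B"], [1.0, 10.0], [3.0, 4.0])
    groups = RangeGroups(
        groups=[RangeGroup((0.0, 5.0), ("s1",), 0.0), RangeGroup((5.0, 20.0), ("s2",), 0.0)]
    )
    col = teo_rb_table(prec, groups)
    assert col.per_level == {"A": 6.0, "B": 8.0}


def test_teo_ab_zero_bias_reduces_to_2cv():
    prec = make_precision(["A", "B"], [1.0, 10.0], [3.0, 4.0])
    col = teo_ab_table(prec, 0.0)
    assert col.per_level == {"A": 6.0, "B": 8.0}


def test_teo_ab_minus_2cv_constant_across_published_levels(fixture):
    """The structural signature of the average-bias decomposition: one
    overall bias, so TEo(AB) − 2·within-CV is level-independent."""
    t1 = fixture.table1
    residual = np.asarray(t1.teo_ab) - 2 * np.asarray(t1.within_cv)
    assert np.ptp(residual) <= 0.2 + 1e-9


def test_make_range_groups_partition_and_intervals(default_pairs):
    groups = make_range_groups(default_pairs, n_groups=5)
    all_ids = [sid for g in groups.groups for sid in g.sample_ids]
    assert sorted(all_ids) == sorted(default_pairs.ids)
    bounds = [g.interval for g in groups.groups]
    assert all(lo <= hi for lo, hi in bounds)
    assert all(b1[1] <= b2[0] for b1, b2 in zip(bounds, bounds[1:]))
    sizes = [len(g.sample_ids) for g in groups.groups]
    assert max(sizes) - min(sizes) <= 1


def test_group_bias_grows_with_concentration_under_proportional_bias(rng):
    """A purely proportional inter-lab bias gives every group the same
    percent bias; adding a constant bias inflates the low groups."""
    lab1 = np.sort(rng.uniform(0.3, 30, 200))
    lab2 = lab1 / 1.2
    groups = make_range_groups(
        PairedMeasurements(ids=[str(i) for i in range(200)], lab1=lab1, lab2=lab2),
        n_groups=5,
    )
    expected = 100 * (1.2 - 1) / ((1.2 + 1) / 2)  # ≈ 18.18% at every group
    for g in groups.groups:
        assert g.percent_bias == pytest.approx(expected, abs=1e-9)
    lab2c = np.clip(lab1 - 0.5, 0.01, None)
    groups_c = make_range_groups(
        PairedMeasurements(ids=[str(i) for i in range(200)], lab1=lab1, lab2=lab2c),
        n_groups=5,
    )
    biases = [g.percent_bias for g in groups_c.groups]
    assert biases[0] > biases[-1]


def test_group_for_clamps_and_fills_gaps():
    groups = RangeGroups(
        groups=[RangeGroup((1.0, 2.0), ("a",), 5.0), RangeGroup((4.0, 8.0), ("b",), 7.0)]
    )
    assert groups.group_for(0.1).percent_bias == 5.0   # below → first
    assert groups.group_for(30.0).percent_bias == 7.0  # above → last
    assert groups.group_for(2.5).percent_bias == 5.0   # gap → nearer
    assert groups.group_for(3.5).percent_bias == 7.0


def test_total_error_table_assembly(fixture_panel, default_pairs):
    from assayval.precision import precision_table
    from assayval.recovery import recovery_table

    prec = precision_table(fixture_panel)
    rec = recovery_table(fixture_panel)
    groups = make_range_groups(default_pairs)
    table = total_error_table(prec, rec, groups, overall_percent_bias=10.0)
    assert len(table.rows) == 8
    for row in table.rows:
        assert row.teo_sr is not None and row.teo_rb is not None
        assert row.teo_ab == pytest.approx(
            2 * prec.row(row.label).within_cv + 10.0
        )
    assert set(table.group_map) == {r.label for r in prec.rows}
    partial = total_error_table(prec, rec)
    assert partial.average_rb is None and partial.average_ab is None
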