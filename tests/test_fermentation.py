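"""Calibration fits, inverse prediction, growth and degradation summaries."""

import math

import numpy as np
import pytest

from pulfinder.fermentation_analysis import (
    DegenerateFitError,
    ExtrapolationError,
    GLUCOSE_STANDARDS_MG_ML,
    SEC_MW,
    SEC_STANDARDS_DA,
    SUGAR_STANDARD,
    TimeSeries,
    degradation_metrics,
    fit_line,
    fit_sec_calibration,
    mean_series,
    mw_from_rt,
    read_calibration_csv,
    read_timeseries_csv,
    sugar_concentration,
    summarize_growth,
    write_timeseries_csv,
)

import _oracles


# ---------------------------------------------------------------------------
# fit_line


def test_exact_line_recovered():
    c = fit_line([0, 1, 2], [1, 3, 5])
    assert c.slope == pytest.approx(2.0)
    assert c.intercept == pytest.approx(1.0)
    assert c.r2 == pytest.approx(1.0)


def test_zero_slope_curve_rejected_for_calibration():
    c = fit_line([0, 1], [0, 0])
    assert c.slope == 0.0
    assert not c.accepted
    with pytest.raises(DegenerateFitError):
        sugar_concentration(0.5, c)


def test_identical_x_is_degenerate():
    with pytest.raises(DegenerateFitError):
        fit_line([2, 2, 2], [1, 2, 3])


def test_noisy_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(11)
    x = list(np.linspace(0, 10, 25))
    y = [2.5 * xi - 1.3 + rng.normal(0, 0.5) for xi in x]
    c = fit_line(x, y)
    slope, intercept = _oracles.ols_closed_form(x, y)
    assert c.slope == pytest.approx(slope, abs=1e-10)
    assert c.intercept == pytest.approx(intercept, abs=1e-10)


# ---------------------------------------------------------------------------
# sugar standard curve


def test_inverse_prediction_simple_curve():
    c = fit_line([0, 0.05, 0.1], [0, 0.5, 1.0])  # slope 10, intercept 0
    assert sugar_concentration(0.5, c).value == pytest.approx(0.05)
    assert sugar_concentration(0.5, c, dilution_factor=4).value == pytest.approx(0.2)


def test_absorbance_at_intercept_gives_zero():
    c = fit_line([0, 0.1], [0.08, 1.08])
    p = sugar_concentration(0.08, c)
    assert p.value == pytest.approx(0.0, abs=1e-12)
    assert not p.clipped


def test_below_intercept_clips_to_zero_with_flag():
    c = fit_line([0, 0.1], [0.1, 1.1])
    p = sugar_concentration(0.05, c)
    assert p.value == 0.0
    assert p.clipped


def test_wrong_curve_kind_rejected():
    c = fit_line([10, 20], [5, 4], kind=SEC_MW)
    with pytest.raises(TypeError):
        sugar_concentration(0.5, c)
    c2 = fit_line([0, 0.1], [0, 1], kind=SUGAR_STANDARD)
    with pytest.raises(TypeError):
        mw_from_rt(0.05, c2)


def test_standard_curve_roundtrip_noise_free():
    concs = GLUCOSE_STANDARDS_MG_ML
    absorb = [0.015 + 9.8 * c for c in concs]
    curve = fit_line(concs, absorb)
    for c_true, a in zip(concs, absorb):
        got = sugar_concentration(a, curve).value
        assert got == pytest.approx(c_true, abs=1e-9)


def test_standard_curve_roundtrip_with_noise():
    rng = np.random.default_rng(5)
    concs = GLUCOSE_STANDARDS_MG_ML[1:]  # skip 0 (relative error undefined)
    absorb = [(0.01 + 10.0 * c) * (1 + rng.normal(0, 0.02)) for c in concs]
    curve = fit_line(GLUCOSE_STANDARDS_MG_ML,
                     [0.01 * (1 + rng.normal(0, 0.02))]
                     + list(absorb))
    for c_true in concs:
        pred = sugar_concentration(0.01 + 10.0 * c_true, curve).value
        assert abs(pred - c_true) / c_true < 0.05


# ---------------------------------------------------------------------------
# SEC calibration


def _sec_curve(slope=-0.25, intercept=8.0):
    """Standards placed exactly on a log-line: rt derived from each Mw."""
    rts = [(math.log10(mw) - intercept) / slope for mw in SEC_STANDARDS_DA]
    return fit_sec_calibration(rts, SEC_STANDARDS_DA), rts


def test_sec_roundtrip_on_exact_line():
    curve, rts = _sec_curve()
    assert curve.slope < 0
    for rt, mw in zip(rts, SEC_STANDARDS_DA):
        assert mw_from_rt(rt, curve) == pytest.approx(mw, rel=1e-6)


def test_sec_monotone_decreasing_on_printed_standards():
    # equally spaced synthetic retention times; big molecules elute first
    rts = list(np.linspace(10, 20, len(SEC_STANDARDS_DA)))
    curve = fit_sec_calibration(rts, sorted(SEC_STANDARDS_DA, reverse=True))
    mws = [mw_from_rt(rt, curve) for rt in np.linspace(10, 20, 40)]
    assert all(a > b for a, b in zip(mws, mws[1:]))


def test_sec_roundtrip_with_noise_within_5pct():
    rng = np.random.default_rng(17)
    rts = [(math.log10(mw) - 8.0) / -0.25 * (1 + rng.normal(0, 0.02))
           for mw in SEC_STANDARDS_DA]
    curve = fit_sec_calibration(rts, SEC_STANDARDS_DA)
    for rt, mw in zip(rts, SEC_STANDARDS_DA):
        # log-scale relative error of the recovered log10(Mw)
        assert abs(math.log10(mw_from_rt(rt, curve)) - math.log10(mw)) \
            / math.log10(mw) < 0.05


def test_extrapolation_outside_domain_raises():
    curve, rts = _sec_curve()
    with pytest.raises(ExtrapolationError, match="domain"):
        mw_from_rt(max(rts) + 100.0, curve)


# ---------------------------------------------------------------------------
# degradation metrics

TIMES = (0.0, 12.0, 24.0, 48.0, 72.0)


def _series(values, analyte="Mw", substrate="x"):
    return TimeSeries(analyte, substrate, tuple(zip(TIMES, values)))


def test_percent_drop_laminarin_series():
    v = (23598.8, 22254.13, 20559.55, 20319.72, 18203.04)
    m = degradation_metrics(_series(v))
    # independent arithmetic: 100 * (23598.8 - 18203.04) / 23598.8
    assert m.percent_drop == pytest.approx(22.86455, abs=1e-3)
    assert m.absolute_drop == pytest.approx(5395.76, abs=1e-6)


def test_steepest_interval_php_series():
    v = (433812.2, 288126.6, 201151.1, 180726.9, 178095.5)
    m = degradation_metrics(_series(v))
    assert m.steepest_interval == (0.0, 12.0)


def test_constant_series_zero_drop():
    m = degradation_metrics(_series((5.0, 5.0, 5.0, 5.0, 5.0)))
    assert m.percent_drop == 0.0
    assert m.absolute_drop == 0.0


def test_first_value_zero_is_undefined():
    with pytest.raises(ValueError):
        degradation_metrics(_series((0.0, 1.0, 1.0, 1.0, 1.0)))


def test_percent_drop_invariant_under_rescaling():
    v = (400.0, 300.0, 250.0, 220.0, 210.0)
    m1 = degradation_metrics(_series(v))
    m2 = degradation_metrics(_series(tuple(x * 37.5 for x in v)))
    assert m1.percent_drop == pytest.approx(m2.percent_drop)
    assert m1.steepest_interval == m2.steepest_interval


def test_tie_resolves_to_earliest_interval():
    s = TimeSeries("Mw", "x", ((0.0, 10.0), (1.0, 8.0), (2.0, 6.0)))
    assert degradation_metrics(s).steepest_interval == (0.0, 1.0)


# ---------------------------------------------------------------------------
# growth summary


def _logistic_series(k=0.8, r=0.3, t0=12.0, times=TIMES):
    vals = tuple(k / (1 + math.exp(-r * (t - t0))) for t in times)
    return TimeSeries("OD600", "x", tuple(zip(times, vals)))


def test_logistic_growth_phases():
    s = _logistic_series()
    g = summarize_growth(s)
    assert g.lag_end <= 12.0
    t95 = 12.0 + math.log(19) / 0.3  # time at 95% of carrying capacity
    assert g.stationary_start >= t95
    assert g.max_value == pytest.approx(max(s.values))
    assert not g.no_growth


def test_flat_series_flags_no_growth():
    s = TimeSeries("OD600", "x", tuple((t, 0.1) for t in TIMES))
    g = summarize_growth(s)
    assert g.no_growth
    assert g.lag_end == TIMES[-1]


def test_monotone_rise_without_plateau_flagged():
    s = TimeSeries("OD600", "x", tuple((t, 0.01 * t + 0.1) for t in TIMES))
    g = summarize_growth(s)
    assert g.no_plateau
    assert g.stationary_start == TIMES[-1]


def test_mean_series_averages_replicates():
    a = TimeSeries("OD600", "x", ((0.0, 0.1), (1.0, 0.3)), "r1")
    b = TimeSeries("OD600", "x", ((0.0, 0.3), (1.0, 0.5)), "r2")
    m = mean_series([a, b])
    assert m.values == (pytest.approx(0.2), pytest.approx(0.4))


def test_timeseries_invariants():
    with pytest.raises(ValueError):
        TimeSeries("OD600", "x", ((1.0, 0.1), (1.0, 0.2)))
    with pytest.raises(ValueError):
        TimeSeries("OD600", "x", ((0.0, -0.1), (1.0, 0.2)))


# ---------------------------------------------------------------------------
# CSV round-trips


def test_timeseries_csv_roundtrip(tmp_path):
    s = [_logistic_series(), _series((10.0, 8.0, 6.0, 5.0, 4.5), analyte="total_sugar")]
    path = tmp_path / "ts.csv"
    write_timeseries_csv(s, path)
    back = read_timeseries_csv(path)
    assert {(b.analyte, b.substrate) for b in back} == \
           {("OD600", "x"), ("total_sugar", "x")}
    got = {b.analyte: b.points for b in back}
    for orig in s:
        for (t0, v0), (t1, v1) in zip(orig.points, got[orig.analyte]):
            assert t0 == t1 and v0 == pytest.approx(v1)


def test_calibration_csv_fits_one_curve_per_kind(tmp_path):
    path = tmp_path / "cal.csv"
    path.write_text(
        "x,y,kind\n0,0.0,sugar_standard\n0.05,0.5,sugar_standard\n"
        "0.1,1.0,sugar_standard\n10,5.5,sec_mw\n20,3.0,sec_mw\n"
    )
    curves = read_calibration_csv(path)
    assert curves["sugar_standard"].slope == pytest.approx(10.0)
    assert curves["sec_mw"].slope == pytest.approx(-0.25)
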