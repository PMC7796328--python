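"""Henderson–Hasselbalch titration, BCECF calibration fit and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlfc.em_calibration import CalibrationError
from tlfc.kinetics import KineticTrace, ph_htf_schedule
from tlfc.ph_calibration import (
    PhCalibrationFit,
    classify_delta_ph,
    fit_ph_calibration,
    hh_base_fraction,
    interpolate_ph,
    koh_addition_amount,
    koh_titration_schedule,
    nh4cl_responsiveness,
)

# representative published calibration line: log10(F) = m*pH + c
LINE_M, LINE_C = -0.29, -1.93


def test_half_titration_at_pka():
    assert hh_base_fraction(7.55, 7.55) == pytest.approx(0.5)


def test_base_fraction_at_ph_6():
    assert hh_base_fraction(6.0, 7.55) == pytest.approx(0.02741, abs=5e-6)


def test_base_fraction_saturates():
    assert hh_base_fraction(20.0, 7.55) == pytest.approx(1.0, abs=1e-6)
    assert hh_base_fraction(-5.0, 7.55) == pytest.approx(0.0, abs=1e-6)


@settings(deadline=None, max_examples=50)
@given(d=st.floats(min_value=0, max_value=5), pka=st.floats(min_value=4, max_value=10))
def test_base_fraction_is_symmetric_about_pka(d, pka):
    assert hh_base_fraction(pka + d, pka) + hh_base_fraction(pka - d, pka) == pytest.approx(1.0)


def test_base_fraction_is_monotone():
    phs = np.linspace(4, 10, 50)
    fracs = [hh_base_fraction(p) for p in phs]
    assert (np.diff(fracs) > 0).all()


# ---------------------------------------------------------------------------
# KOH additions


def test_zero_step_needs_no_base():
    assert koh_addition_amount(25, 1.0, 6.5, 6.5).amount_umol == pytest.approx(0.0)


def test_first_ladder_step_by_hand():
    """25 mM HEPES, 1 mL, 6.00 -> 6.25 at pKa 7.55 takes 0.508 umol KOH."""
    step = koh_addition_amount(25.0, 1.0, 6.00, 6.25)
    by_hand = 25.0 * 1.0 * (1 / (1 + 10**1.30) - 1 / (1 + 10**1.55))
    assert step.amount_umol == pytest.approx(by_hand, rel=1e-12)
    assert step.amount_umol == pytest.approx(0.508, abs=1e-3)


def test_ladder_amounts_telescope_to_the_closed_form():
    steps = koh_titration_schedule(25.0, 1.0)
    assert len(steps) == 8
    total = sum(s.amount_umol for s in steps)
    closed = 25.0 * 1.0 * (hh_base_fraction(8.0) - hh_base_fraction(6.0))
    assert total == pytest.approx(closed, abs=1e-12)


def test_lowering_ph_with_base_is_an_error():
    with pytest.raises(ValueError):
        koh_addition_amount(25, 1.0, 7.0, 6.5)


def test_stock_volume_is_amount_over_concentration():
    step = koh_addition_amount(25.0, 1.0, 6.0, 6.25, stock_mM=500.0)
    assert step.volume_uL == pytest.approx(step.amount_umol / 0.5)


# ---------------------------------------------------------------------------
# fit and inversion


def ladder_points(m=LINE_M, c=LINE_C):
    phs = np.arange(6.0, 8.01, 0.25)
    return [(ph, 10 ** (m * ph + c)) for ph in phs]


def test_fit_recovers_an_exact_generating_line():
    fit = fit_ph_calibration(ladder_points())
    assert fit.slope == pytest.approx(LINE_M, rel=1e-9)
    assert fit.intercept == pytest.approx(LINE_C, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_positive_slope_lines_are_accepted_too():
    fit = fit_ph_calibration(ladder_points(m=0.5, c=0.5))
    assert fit.slope == pytest.approx(0.5, rel=1e-9)


def test_non_positive_fluorescence_is_an_error():
    points = ladder_points()
    points[3] = (points[3][0], 0.0)
    with pytest.raises(CalibrationError, match="non-positive"):
        fit_ph_calibration(points)


def test_too_few_points_is_an_error():
    with pytest.raises(CalibrationError, match=">= 4"):
        fit_ph_calibration(ladder_points()[:3])


@pytest.mark.parametrize("seed", range(30))
def test_noisy_fit_matches_normal_equations_oracle(seed):
    rng = np.random.default_rng(seed)
    phs = np.arange(6.0, 8.01, 0.25)
    log_f = LINE_M * phs + LINE_C + rng.normal(0, 0.02, len(phs))
    fit = fit_ph_calibration(list(zip(phs, 10**log_f)), r2_min=0.0)
    design = np.column_stack([phs, np.ones_like(phs)])
    slope, intercept = np.linalg.solve(design.T @ design, design.T @ log_f)
    assert fit.slope == pytest.approx(slope, rel=1e-9)
    assert fit.intercept == pytest.approx(intercept, rel=1e-9)


def test_inversion_recovers_the_basal_ph():
    """log10 F = -3.8904 on the published line inverts to pHi 6.76."""
    fit = fit_ph_calibration(ladder_points())
    assert interpolate_ph(fit, 10**-3.8904) == pytest.approx(6.76, abs=1e-3)


@settings(deadline=None, max_examples=50)
@given(ph=st.floats(min_value=6.0, max_value=8.0))
def test_interpolation_inverts_the_forward_model(ph):
    fit = fit_ph_calibration(ladder_points())
    assert interpolate_ph(fit, fit.predict(ph)) == pytest.approx(ph, abs=1e-9)


def test_extrapolation_warns_but_returns():
    fit = fit_ph_calibration(ladder_points())
    with pytest.warns(UserWarning, match="extrapolating"):
        value = interpolate_ph(fit, fit.predict(8.6))
    assert value == pytest.approx(8.6, abs=1e-9)


def test_calibration_self_consistency():
    """Each titration point's own fluorescence interpolates back to its pHe."""
    rng = np.random.default_rng(1)
    phs = np.arange(6.0, 8.01, 0.25)
    points = [(ph, 10 ** (0.5 * ph + 0.5 + rng.normal(0, 0.005))) for ph in phs]
    fit = fit_ph_calibration(points)
    assert fit.r_squared >= 0.99
    for ph, f in points:
        assert interpolate_ph(fit, f) == pytest.approx(ph, abs=0.05)


def test_zero_slope_is_an_error():
    flat = PhCalibrationFit(0.0, 1.0, 1.0, 0.0, [(6.0, 10.0)] * 4)
    with pytest.raises(CalibrationError, match="zero"):
        interpolate_ph(flat, 10.0)


# ---------------------------------------------------------------------------
# classification and NH4Cl control


@pytest.mark.parametrize(
    "nc, cap, expected",
    [
        (6.58, 6.94, "alkalinized"),  # the typical capacitation response
        (7.0, 7.0, "unchanged"),
        (7.0, 6.85, "acidified"),
        (7.0, 7.1, "unchanged"),  # +0.1 boundary is inclusive
        (7.0, 6.9, "unchanged"),  # -0.1 boundary is inclusive
    ],
)
def test_delta_ph_classification(nc, cap, expected):
    assert classify_delta_ph(nc, cap) == expected


def trace_for_ph(fit, ph_before, ph_after, width=2.0, duration=360.0):
    """Flat fluorescence trace jumping at 120 s between two calibrated pHs."""
    n = int(duration / width)
    t = (np.arange(n) + 0.5) * width
    values = np.where(t < 120.0, fit.predict(ph_before), fit.predict(ph_after))
    return KineticTrace(t, values.astype(float), np.full(n, 1000), width, "fl1_a")


def test_nh4cl_alkalinization_passes_with_its_magnitude():
    fit = fit_ph_calibration(ladder_points(m=0.5, c=0.5))
    check = nh4cl_responsiveness(trace_for_ph(fit, 6.76, 7.32), ph_htf_schedule(), fit)
    assert check.passed
    assert check.magnitude == pytest.approx(0.56, abs=0.01)
    assert check.ph_baseline == pytest.approx(6.76, abs=0.01)
    assert check.ph_post == pytest.approx(7.32, abs=0.01)


def test_flat_trace_fails_the_control():
    fit = fit_ph_calibration(ladder_points(m=0.5, c=0.5))
    check = nh4cl_responsiveness(trace_for_ph(fit, 6.8, 6.8), ph_htf_schedule(), fit)
    assert not check.passed


def test_boundary_magnitude_fails_strictly():
    fit = fit_ph_calibration(ladder_points(m=0.5, c=0.5))
    check = nh4cl_responsiveness(trace_for_ph(fit, 6.8, 6.9), ph_htf_schedule(), fit)
    assert check.magnitude == pytest.approx(0.1, abs=1e-9)
    assert not check.passed


def test_missing_nh4cl_addition_is_an_error():
    from tlfc.kinetics import Addition, StimulusSchedule

    fit = fit_ph_calibration(ladder_points(m=0.5, c=0.5))
    sched = StimulusSchedule([Addition(120.0, "KCl", 1, "mM")], 360.0)
    with pytest.raises(ValueError, match="NH4Cl"):
        nh4cl_responsiveness(trace_for_ph(fit, 6.8, 6.9), sched, fit)
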