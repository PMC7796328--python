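"""Traces, plateau windows, responding-subpopulation medians, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlfc.kinetics import (
    Addition,
    PlateauWindow,
    StimulusSchedule,
    bin_median_trace,
    ca_schedule,
    em_schedule,
    normalize_trace,
    ph_cal_schedule,
    ph_htf_schedule,
    plateau_median,
    plateau_windows,
)

from conftest import make_events


def events_with_fl1(t, fl1):
    return make_events(np.asarray(t, float), fl1_a=np.asarray(fl1, float))


# ---------------------------------------------------------------------------
# bin_median_trace


def test_constant_channel_gives_constant_trace():
    t = np.linspace(0, 9.99, 500)
    trace = bin_median_trace(events_with_fl1(t, np.full_like(t, 500.0)), "fl1_a",
                             bin_width_s=2.0, min_events=1)
    assert np.allclose(trace.median, 500.0)


def test_two_value_bin_median_is_their_midpoint():
    trace = bin_median_trace(events_with_fl1([0.5, 1.5], [100.0, 300.0]), "fl1_a",
                             bin_width_s=2.0, min_events=1)
    assert trace.median[0] == pytest.approx(200.0)


def test_empty_bin_is_flagged_and_excluded():
    t = [0.5, 0.6, 4.5, 4.6]
    trace = bin_median_trace(events_with_fl1(t, [1.0, 2.0, 3.0, 4.0]), "fl1_a",
                             bin_width_s=2.0, duration_s=6.0, min_events=1)
    assert np.isnan(trace.median[1])
    assert trace.counts[1] == 0
    assert len(trace.window_values(PlateauWindow(2.0, 4.0))) == 0


def test_missing_channel_is_an_error():
    with pytest.raises(KeyError, match="nope"):
        bin_median_trace(make_events([0.0, 1.0]), "nope")


@pytest.mark.parametrize("seed", range(25))
def test_binned_medians_match_brute_force(seed):
    """Per-bin medians agree with an exhaustive per-bin numpy median."""
    rng = np.random.default_rng(seed)
    n = rng.integers(50, 2000)
    t = np.sort(rng.uniform(0, 30, n))
    v = rng.lognormal(8, 1, n)
    width = float(rng.uniform(0.5, 5.0))
    events = events_with_fl1(t, v)
    stored = events["fl1_a"].astype(float)  # intensities are held in float32
    trace = bin_median_trace(events, "fl1_a", bin_width_s=width, min_events=1)
    for i in range(len(trace.median)):
        lo, hi = i * width, (i + 1) * width
        mask = (t >= lo) & (t < hi) if i < len(trace.median) - 1 else (t >= lo)
        expected = np.median(stored[mask]) if mask.any() else np.nan
        if np.isnan(expected):
            assert np.isnan(trace.median[i])
        else:
            assert trace.median[i] == pytest.approx(expected, rel=1e-9)


def test_binning_is_permutation_invariant_within_bins():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 10, 400))
    v = rng.lognormal(8, 1, 400)
    a = bin_median_trace(events_with_fl1(t, v), "fl1_a", min_events=1)
    # shuffle values within each bin: medians must not change
    idx = (t / 2.0).astype(int)
    v2 = v.copy()
    for b in np.unique(idx):
        sel = np.flatnonzero(idx == b)
        v2[sel] = rng.permutation(v2[sel])
    b_trace = bin_median_trace(events_with_fl1(t, v2), "fl1_a", min_events=1)
    assert np.allclose(a.median, b_trace.median, equal_nan=True)


# ---------------------------------------------------------------------------
# plateau windows


def test_window_arithmetic_follows_the_settle_rule():
    sched = StimulusSchedule([Addition(240.0, "KCl", 10, "mM")], duration_s=600.0)
    (w,) = plateau_windows(sched, settle_s=90, width_s=30)
    assert (w.start_s, w.end_s) == (330.0, 360.0)


def test_default_windows_end_at_the_next_addition():
    sched = em_schedule()
    windows = plateau_windows(sched)
    addition_times = [a.time_s for a in sched.additions] + [sched.duration_s]
    for w, next_t in zip(windows, addition_times[1:]):
        assert w.end_s == next_t


def test_overlapping_window_is_an_error():
    sched = em_schedule()
    with pytest.raises(ValueError, match="overlaps"):
        plateau_windows(sched, settle_s=110, width_s=30)


def test_schedule_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        StimulusSchedule([Addition(240, "a", 1, "x"), Addition(240, "b", 1, "x")], 600)
    with pytest.raises(ValueError, match="baseline"):
        StimulusSchedule([Addition(30, "a", 1, "x")], 600)
    with pytest.raises(ValueError, match="duration"):
        StimulusSchedule([Addition(700, "a", 1, "x")], 600)


def test_shipped_schedules_are_valid():
    for sched in (em_schedule(), ca_schedule(), ph_htf_schedule(), ph_cal_schedule()):
        assert sched.additions[0].time_s >= sched.baseline_s
        assert sched.additions[-1].time_s < sched.duration_s
    # the stepwise-titration protocols read settled plateaus per addition
    for sched in (em_schedule(), ph_htf_schedule(), ph_cal_schedule()):
        plateau_windows(sched)  # must not raise


# ---------------------------------------------------------------------------
# plateau_median


def test_unimodal_responding_equals_all():
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(0, 30, 5000))
    v = 1e4 * np.exp(0.25 * rng.standard_normal(5000))
    ev = events_with_fl1(t, v)
    w = PlateauWindow(0, 30)
    assert plateau_median(ev, "fl1_a", w, "responding") == plateau_median(ev, "fl1_a", w, "all")


def test_responding_mode_median_tracks_the_responders():
    """80% responders at 1e4 / 20% non-responders at 1e3: the responding
    median is within 5% of the responders-only brute-force median."""
    rng = np.random.default_rng(2)
    n = 20_000
    responder = rng.random(n) < 0.8
    v = np.where(responder, 1e4, 1e3) * np.exp(0.25 * rng.standard_normal(n))
    t = np.sort(rng.uniform(0, 30, n))
    ev = events_with_fl1(t, v)
    est = plateau_median(ev, "fl1_a", PlateauWindow(0, 30), "responding")
    truth = np.median(v[responder])
    assert est == pytest.approx(truth, rel=0.05)


def test_too_few_events_is_an_error():
    ev = events_with_fl1(np.linspace(0, 29, 10), np.full(10, 1e4))
    with pytest.raises(ValueError, match="10 events"):
        plateau_median(ev, "fl1_a", PlateauWindow(0, 30), min_events=200)


def test_plateau_median_rejects_unknown_subpop():
    ev = events_with_fl1([0.0, 1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="subpop"):
        plateau_median(ev, "fl1_a", PlateauWindow(0, 2), subpop="nonsense", min_events=1)


# ---------------------------------------------------------------------------
# normalize_trace


def flat_trace(values, width=2.0):
    values = np.asarray(values, float)
    t = (np.arange(len(values)) + 0.5) * width
    from tlfc.kinetics import KineticTrace

    return KineticTrace(t, values, np.full(len(values), 100), width, "fl1_a")


def test_normalizing_the_baseline_itself_gives_zero():
    trace = flat_trace(np.full(60, 100.0))
    norm = normalize_trace(trace, PlateauWindow(0, 120))
    assert np.allclose(norm.median, 0.0)
    assert norm.normalized


def test_normalization_arithmetic():
    trace = flat_trace([100.0] * 60 + [290.0, 50.0])
    norm = normalize_trace(trace, PlateauWindow(0, 120))
    assert norm.median[60] == pytest.approx(1.90)
    assert norm.median[61] == pytest.approx(-0.5)


def test_non_positive_baseline_is_an_error():
    trace = flat_trace(np.zeros(60))
    with pytest.raises(ValueError, match="F0 must be positive"):
        normalize_trace(trace, PlateauWindow(0, 120))


@settings(deadline=None, max_examples=30)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_normalization_is_scale_equivariant(scale):
    """Multiplying all raw intensities by c > 0 leaves (F-F0)/F0 unchanged."""
    values = np.array([100.0] * 60 + [250.0, 80.0, 310.0])
    a = normalize_trace(flat_trace(values), PlateauWindow(0, 120))
    b = normalize_trace(flat_trace(values * scale), PlateauWindow(0, 120))
    assert np.allclose(a.median, b.median, rtol=1e-9, atol=1e-12)
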