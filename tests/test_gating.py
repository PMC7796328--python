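"""Gating: debris/singlet/viability filters and the valley detector."""

import numpy as np
import pytest

from tlfc.fcs_io import EventTable
from tlfc.gating import (
    GateConfig,
    GatingError,
    apply_debris_gate,
    apply_gates,
    apply_singlet_gate,
    apply_viability_gate,
    auto_viability_threshold,
    log_intensity_valley,
)

from conftest import make_events


def lognormal_events(rng, n, fsc_med, ssc_med, fl1_med, sigma=0.25, ratio=0.9):
    fsc = fsc_med * np.exp(sigma * rng.standard_normal(n))
    return EventTable.from_arrays(
        np.sort(rng.uniform(0, 10, n)),
        fsc,
        fsc * ratio,
        ssc_med * np.exp(sigma * rng.standard_normal(n)),
        fl1_med * np.exp(sigma * rng.standard_normal(n)),
        np.full(n, 1e5),
    )


def test_zero_thresholds_are_a_no_op():
    events = make_events([0.0, 1.0, 2.0])
    cfg = GateConfig(fsc_min=0, ssc_min=0)
    assert len(apply_debris_gate(events, cfg)) == len(events)


def test_debris_gate_recovers_exact_ground_truth():
    """Cells above and debris below the thresholds separate exactly."""
    rng = np.random.default_rng(0)
    n_cells, n_debris = 100, 50
    t = np.sort(rng.uniform(0, 10, n_cells + n_debris))
    is_cell = np.zeros(n_cells + n_debris, bool)
    is_cell[:n_cells] = True
    rng.shuffle(is_cell)
    fsc = np.where(is_cell, 1e5, 3e3)
    ssc = np.where(is_cell, 5e4, 1e3)
    events = EventTable.from_arrays(t, fsc, 0.9 * fsc, ssc, np.full_like(t, 1e4), np.full_like(t, 1e5))
    out = apply_debris_gate(events, GateConfig(fsc_min=2e4, ssc_min=5e3))
    assert len(out) == n_cells
    assert np.allclose(out["fsc_a"], 1e5)


def test_thresholds_above_everything_warn_and_empty():
    events = make_events([0.0, 1.0])
    with pytest.warns(UserWarning, match="removed every event"):
        out = apply_debris_gate(events, GateConfig(fsc_min=1e9, ssc_min=1e9))
    assert len(out) == 0


def test_singlet_gate_removes_simulated_doublets():
    """>= 99% of doublets (doubled area, sub-additive height) are cut."""
    rng = np.random.default_rng(1)
    n = 10_000
    is_doublet = rng.random(n) < 0.10
    fsc = 1e5 * np.exp(0.2 * rng.standard_normal(n))
    ratio = rng.normal(0.9, 0.03, n)
    fsc_h = fsc * ratio
    fsc[is_doublet] *= 2.0
    fsc_h[is_doublet] *= 1.2  # ratio ends up near 0.54
    events = EventTable.from_arrays(
        np.sort(rng.uniform(0, 10, n)), fsc, fsc_h, np.full(n, 5e4),
        np.full(n, 1e4), np.full(n, 1e5),
    )
    out = apply_singlet_gate(events, GateConfig(singlet_band=(0.75, 1.05)))
    kept_ratio = out["fsc_h"] / out["fsc_a"]
    assert (kept_ratio >= 0.75).all() and (kept_ratio <= 1.05).all()
    n_doublets_kept = np.sum(np.isin(out["fsc_a"], fsc[is_doublet].astype(np.float32)))
    assert n_doublets_kept <= 0.01 * is_doublet.sum()


def test_mid_band_events_all_retained():
    events = make_events([0.0, 1.0, 2.0], fsc_a=np.full(3, 1e5), fsc_h=np.full(3, 9e4))
    out = apply_singlet_gate(events, GateConfig(singlet_band=(0.75, 1.05)))
    assert len(out) == 3


def test_wide_band_is_identity():
    events = make_events(np.arange(5.0))
    out = apply_singlet_gate(events, GateConfig(singlet_band=(1e-6, 1e6)))
    assert len(out) == 5


def test_singlet_gate_requires_positive_fsc():
    events = make_events([0.0], fsc_a=np.array([0.0]))
    with pytest.raises(GatingError, match="fsc_a > 0"):
        apply_singlet_gate(events, GateConfig())


def test_auto_threshold_lands_between_killed_and_viable_modes():
    rng = np.random.default_rng(2)
    stained = lognormal_events(rng, 20_000, 1e5, 5e4, fl1_med=1e4)
    killed = lognormal_events(rng, 20_000, 1e5, 5e4, fl1_med=1e2)
    thr = auto_viability_threshold(stained, killed)
    assert 1e2 < thr < 1e4


def test_auto_threshold_rejects_identical_distributions():
    rng = np.random.default_rng(3)
    a = lognormal_events(rng, 5_000, 1e5, 5e4, fl1_med=1e3)
    b = lognormal_events(rng, 5_000, 1e5, 5e4, fl1_med=1e3)
    with pytest.raises(GatingError, match="not separable"):
        auto_viability_threshold(a, b)


def test_auto_threshold_disjoint_support_falls_in_the_gap():
    rng = np.random.default_rng(4)
    killed = lognormal_events(rng, 5_000, 1e5, 5e4, fl1_med=1e2, sigma=0.05)
    viable = lognormal_events(rng, 5_000, 1e5, 5e4, fl1_med=1e4, sigma=0.05)
    thr = auto_viability_threshold(viable, killed)
    assert killed["fl1_a"].max() < thr < viable["fl1_a"].min()


def test_valley_detector_ignores_unimodal_noise():
    rng = np.random.default_rng(5)
    values = 1e4 * np.exp(0.25 * rng.standard_normal(20_000))
    assert log_intensity_valley(values) is None


def test_valley_detector_splits_separated_modes():
    rng = np.random.default_rng(6)
    values = np.concatenate([
        1e2 * np.exp(0.3 * rng.standard_normal(5_000)),
        1e4 * np.exp(0.3 * rng.standard_normal(5_000)),
    ])
    thr = log_intensity_valley(values)
    assert thr is not None and 1e2 < thr < 1e4


def test_gates_are_idempotent_filters(em_run_65, sim_config):
    """Re-applying the fixed gate order changes nothing; output is a subset."""
    events, _ = em_run_65
    cfg = GateConfig()
    once, retention = apply_gates(events, cfg)
    twice, retention2 = apply_gates(once, cfg)
    assert len(twice) == len(once)
    assert once.data["time_s"].equals(twice.data["time_s"])
    assert 0 < retention["total"] <= 1
    assert retention2["total"] == pytest.approx(1.0)


def test_viable_singlet_recall_and_precision(em_run_65):
    """Against simulator ground truth, the gate chain keeps viable singlets
    with recall and precision >= 0.95."""
    events, _ = em_run_65
    gated, _ = apply_gates(events, GateConfig())
    labels = events.labels
    viable = (labels == "viable_responder") | (labels == "viable_nonresponder")
    kept_labels = gated.labels
    kept_viable = (kept_labels == "viable_responder") | (kept_labels == "viable_nonresponder")
    recall = kept_viable.sum() / viable.sum()
    precision = kept_viable.sum() / len(gated)
    assert recall >= 0.95
    assert precision >= 0.95


def test_viability_gate_auto_requires_reference():
    events = make_events([0.0, 1.0])
    with pytest.raises(GatingError, match="heat-killed"):
        apply_viability_gate(events, GateConfig(viability_threshold="auto"))


def test_gate_config_validation():
    with pytest.raises(ValueError):
        GateConfig(singlet_band=(1.0, 0.5))
    with pytest.raises(ValueError):
        GateConfig(fsc_min=-1)
    with pytest.raises(ValueError):
        GateConfig(viability_threshold="magic")
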