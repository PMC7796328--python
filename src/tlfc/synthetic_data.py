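"""Seeded, ground-truth-labelled synthetic time-lapse event streams.

The generator emulates what a peristaltic-pump cytometer records during
the three protocols: a Poisson stream of independent single-cell events
(each cell passes the laser once, so there is no per-cell trajectory)
whose fluorescence statistics shift as reagents are added.  Event rate
defaults to 700 events/s — the 14 µL/min flow rate times the 3×10⁶
cells/mL working concentration.  Per-event intensities carry
multiplicative log-normal noise; dead cells, debris and doublets are
drawn from their own class models and labelled so gates can be scored
against ground truth.

The dye-response generating models are, by construction, exactly the
model classes the calibrations assume: fluorescence linear in Em for
the voltage dye and log-linear in pH for BCECF.  Population responses
relax exponentially toward each stimulus segment's target.  This
isolates pipeline correctness; what it deliberately does not emulate
(dye saturation, drift, autocorrelated noise) is documented in the
methods note.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .em_calibration import nernst_em
from .fcs_io import EventTable
from .kinetics import (
    StimulusSchedule,
    ca_schedule,
    em_schedule,
    ph_cal_schedule,
    ph_htf_schedule,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_em_run",
    "simulate_ph_run",
    "simulate_ca_run",
    "DEFAULT_EVENT_RATE_HZ",
]

#: 14 µL/min × 3×10⁶ cells/mL ≈ 700 events/s
DEFAULT_EVENT_RATE_HZ = 700.0


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study conditions.

    Event fractions must sum to 1.  Intensity scales are log-normal:
    ``*_sigma`` values are natural-log standard deviations.  The noise
    CV applies multiplicatively per event (median-unbiased: the noise
    factor has median 1).
    """

    event_rate_hz: float = DEFAULT_EVENT_RATE_HZ
    seed: int = 0

    # event-class mixture
    viable_fraction: float = 0.80
    dead_fraction: float = 0.08
    debris_fraction: float = 0.07
    doublet_fraction: float = 0.05
    #: fraction of viable cells that follow the stimulus (ionophores act
    #: on nearly every intact cell)
    responder_fraction: float = 0.90

    # scatter models (a.u.)
    cell_fsc_median: float = 1e5
    cell_fsc_sigma: float = 0.20
    cell_ssc_median: float = 5e4
    cell_ssc_sigma: float = 0.25
    singlet_ratio_mean: float = 0.90
    singlet_ratio_sd: float = 0.03
    debris_fsc_median: float = 3e3
    debris_ssc_median: float = 1e3
    debris_sigma: float = 0.5
    #: doublets: two cells in one pulse — area doubles, height is sub-additive
    doublet_height_factor: float = 1.2

    # fluorescence models
    noise_cv: float = 0.25
    viable_fl1_baseline: float = 1e4
    dead_fl1_median: float = 1e2
    dead_fl1_sigma: float = 0.4
    background_fl_median: float = 50.0
    # voltage dye: F = em_slope·Em + em_intercept (a.u., a.u./mV)
    em_slope: float = -10682.4
    em_intercept: float = -264308.0
    em_tau_s: float = 20.0
    # BCECF: log10 F = ph_slope·pH + ph_intercept
    ph_slope: float = 0.5
    ph_intercept: float = 0.5
    ph_tau_s: float = 20.0
    # progesterone transient shape (normalized scale)
    ca_tau_rise_s: float = 10.0
    ca_tau_decay_s: float = 60.0
    ca_plateau_fraction: float = 0.4
    ca_iono_max: float = 3.0
    ca_mn_min: float = -0.8

    def __post_init__(self) -> None:
        total = (
            self.viable_fraction
            + self.dead_fraction
            + self.debris_fraction
            + self.doublet_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event-class fractions sum to {total}, expected 1")
        if self.event_rate_hz <= 0:
            raise ValueError("event rate must be positive")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        for name in ("cell_fsc_sigma", "cell_ssc_sigma", "debris_sigma", "dead_fl1_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class GroundTruth:
    """Truth record serialized alongside simulated recordings."""

    protocol: str
    seed: int
    truth: dict = field(default_factory=dict)
    class_counts: dict = field(default_factory=dict)
    generating_model: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# building blocks


def _noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Median-1 multiplicative log-normal factor with the given CV."""
    if cv == 0:
        return np.ones(n, dtype=np.float32)
    sigma = np.float32(np.sqrt(np.log1p(cv**2)))
    return np.exp(sigma * rng.standard_normal(n, dtype=np.float32))


#: population signals are smooth on the seconds scale; evaluating them on
#: this grid and interpolating per event is exact to well under the noise
_SIGNAL_GRID_S = 0.1


def _on_grid(duration_s: float, fn):
    """Evaluate a time-signal callable on the grid; returns (grid, values)."""
    grid = np.arange(0.0, duration_s + _SIGNAL_GRID_S, _SIGNAL_GRID_S)
    return grid, fn(grid)


def _interp(t: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.interp(t, grid, values)


def _relaxation(
    t: np.ndarray, change_times: list[float], targets: list[float], start: float, tau: float
) -> np.ndarray:
    """Piecewise exponential relaxation toward successive targets.

    Before the first change time the value holds at ``start``; each
    subsequent segment relaxes from the previous segment's end value
    toward its target with time constant ``tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    starts = [start]
    for k, (t0, target) in enumerate(zip(change_times, targets)):
        t1 = change_times[k + 1] if k + 1 < len(change_times) else np.inf
        seg = min(t1, np.inf) - t0
        end = target + (starts[-1] - target) * (np.exp(-seg / tau) if np.isfinite(seg) else 0.0)
        starts.append(end)
    out = np.full_like(t, float(start), dtype=float)
    for k, (t0, target) in enumerate(zip(change_times, targets)):
        t1 = change_times[k + 1] if k + 1 < len(change_times) else np.inf
        m = (t >= t0) & (t < t1)
        out[m] = target + (starts[k] - target) * np.exp(-(t[m] - t0) / tau)
    return out


_LABELS = ("viable_responder", "viable_nonresponder", "dead", "debris", "doublet")


def _base_events(cfg: SimConfig, rng: np.random.Generator, duration_s: float):
    """Arrival times, class labels and scatter channels for one recording."""
    n = int(rng.poisson(cfg.event_rate_hz * duration_s))
    t = np.sort(rng.uniform(0.0, duration_s, n))
    probs = np.array(
        [
            cfg.viable_fraction * cfg.responder_fraction,
            cfg.viable_fraction * (1 - cfg.responder_fraction),
            cfg.dead_fraction,
            cfg.debris_fraction,
            cfg.doublet_fraction,
        ]
    )
    cls = np.searchsorted(np.cumsum(probs / probs.sum()), rng.random(n), side="right")
    cls = np.minimum(cls, len(_LABELS) - 1).astype(np.int8)

    fsc = cfg.cell_fsc_median * np.exp(
        np.float32(cfg.cell_fsc_sigma) * rng.standard_normal(n, dtype=np.float32)
    )
    ssc = cfg.cell_ssc_median * np.exp(
        np.float32(cfg.cell_ssc_sigma) * rng.standard_normal(n, dtype=np.float32)
    )
    ratio = (
        cfg.singlet_ratio_mean
        + cfg.singlet_ratio_sd * rng.standard_normal(n, dtype=np.float32)
    ).clip(0.05)
    fsc_h = fsc * ratio

    debris = cls == 3
    n_deb = int(debris.sum())
    deb_noise = np.exp(
        np.float32(cfg.debris_sigma) * rng.standard_normal(2 * n_deb, dtype=np.float32)
    )
    fsc[debris] = cfg.debris_fsc_median * deb_noise[:n_deb]
    ssc[debris] = cfg.debris_ssc_median * deb_noise[n_deb:]
    fsc_h[debris] = fsc[debris] * ratio[debris]

    doublet = cls == 4
    fsc[doublet] *= 2.0
    fsc_h[doublet] *= cfg.doublet_height_factor  # height / (2·area) ≈ 0.54·ratio

    labels = pd.Categorical.from_codes(cls, categories=list(_LABELS))
    return t, cls, fsc, fsc_h, ssc, labels


def _fill_fl(cfg, rng, t, cls, responding_signal, nonresponding_signal):
    """Per-event fluorescence: signal for viable cells, class models otherwise.

    ``responding_signal``/``nonresponding_signal`` are the noise-free
    population median intensities evaluated at the event times.
    """
    n = len(t)
    fl = np.empty(n)
    fl[cls == 0] = responding_signal[cls == 0]
    fl[cls == 1] = nonresponding_signal[cls == 1]
    dead = cls == 2
    fl[dead] = cfg.dead_fl1_median * np.exp(cfg.dead_fl1_sigma * rng.standard_normal(dead.sum()))
    debris = cls == 3
    fl[debris] = cfg.background_fl_median * np.exp(
        cfg.debris_sigma * rng.standard_normal(debris.sum())
    )
    doublet = cls == 4
    fl[doublet] = 2.0 * responding_signal[doublet]
    fl *= _noise(rng, cfg.noise_cv, n)
    return np.maximum(fl, 0.0)


def _class_counts(labels: np.ndarray) -> dict[str, int]:
    return {lbl: int((labels == lbl).sum()) for lbl in _LABELS}


def _ca_trace(t, schedule: StimulusSchedule, peak, cfg: SimConfig):
    """Normalized-scale calcium generating trace for the Pg protocol.

    Baseline 0; a progesterone transient rising with ``ca_tau_rise_s``
    to ``peak`` then decaying to ``ca_plateau_fraction``·peak; an
    ionomycin step to ``ca_iono_max``; and a Mn²⁺ quench to
    ``ca_mn_min``.
    """
    out = np.zeros_like(t, dtype=float)
    pg = schedule.find("progesterone")
    iono = schedule.find("ionomycin")
    mn = schedule.find("MnCl2")
    t_pg, t_iono, t_mn = pg.time_s, iono.time_s, mn.time_s

    m = (t >= t_pg) & (t < t_iono)
    dt = t[m] - t_pg
    rise = 1.0 - np.exp(-dt / cfg.ca_tau_rise_s)
    t_top = 5.0 * cfg.ca_tau_rise_s  # effectively at peak
    decay = np.where(
        dt <= t_top,
        1.0,
        cfg.ca_plateau_fraction
        + (1 - cfg.ca_plateau_fraction) * np.exp(-(dt - t_top) / cfg.ca_tau_decay_s),
    )
    out[m] = peak * rise * decay

    plateau_end = peak * (
        cfg.ca_plateau_fraction
        + (1 - cfg.ca_plateau_fraction) * np.exp(-(t_iono - t_pg - t_top) / cfg.ca_tau_decay_s)
    )
    m = (t >= t_iono) & (t < t_mn)
    out[m] = cfg.ca_iono_max + (plateau_end - cfg.ca_iono_max) * np.exp(
        -(t[m] - t_iono) / 5.0
    )
    m = t >= t_mn
    out[m] = cfg.ca_mn_min + (cfg.ca_iono_max - cfg.ca_mn_min) * np.exp(-(t[m] - t_mn) / 5.0)
    return out


def _em_fl1_trace(t, schedule: StimulusSchedule, cfg: SimConfig):
    """Mild voltage-evoked calcium dynamics on fl1 during the Em protocol.

    Valinomycin hyperpolarization produces a transient Fluo3 dip
    (minimum near 60 s post-addition) with partial recovery; each KCl
    depolarization step evokes a small transient influx.  Amplitudes
    are modest and fixed — this channel is qualitative context, not a
    calibrated readout.
    """
    out = np.zeros_like(t, dtype=float)
    for addition in schedule.additions:
        dt = t - addition.time_s
        m = dt >= 0
        if not m.any():
            continue
        if addition.compound == "valinomycin":
            # double-exponential dip, normalized to depth 0.3
            shape = np.exp(-dt[m] / 90.0) - np.exp(-dt[m] / 25.0)
            if shape.max() > 0:
                out[m] -= 0.3 * shape / shape.max()
        else:
            shape = np.exp(-dt[m] / 40.0) - np.exp(-dt[m] / 8.0)
            if shape.max() > 0:
                out[m] += 0.4 * shape / shape.max()
    return out


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds, kept below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# protocol simulators


def simulate_em_run(
    cfg: SimConfig,
    true_em_mV: float,
    schedule: StimulusSchedule | None = None,
    seed: int | None = None,
) -> tuple[EventTable, GroundTruth]:
    """One membrane-potential recording with a known resting Em.

    Responding viable cells hold ``true_em_mV`` through the baseline,
    then relax (τ = ``em_tau_s``) to the Nernst potential of each K⁺
    step; their disc fluorescence follows the linear generating model.
    Non-responders hold the resting potential throughout.
    """
    if not -100.0 <= true_em_mV <= 0.0:
        raise ValueError(f"true resting Em {true_em_mV} mV outside [-100, 0]")
    schedule = schedule or em_schedule()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t, cls, fsc, fsc_h, ssc, labels = _base_events(cfg, rng, schedule.duration_s)

    times = [a.time_s for a in schedule.additions]
    targets = [nernst_em(a.target) for a in schedule.additions]
    grid, em_g = _on_grid(
        schedule.duration_s,
        lambda g: _relaxation(g, times, targets, true_em_mV, cfg.em_tau_s),
    )
    em_t = _interp(t, grid, em_g)
    f_resp = cfg.em_slope * em_t + cfg.em_intercept
    f_rest = cfg.em_slope * true_em_mV + cfg.em_intercept
    if f_rest <= 0 or np.any(f_resp <= 0):
        raise ValueError(
            "generating line yields non-positive fluorescence over the protocol; "
            "adjust em_slope/em_intercept or the resting Em"
        )
    fl4 = _fill_fl(cfg, rng, t, cls, f_resp, np.full_like(t, f_rest))

    ca = _interp(t, *_on_grid(schedule.duration_s, lambda g: _em_fl1_trace(g, schedule, cfg)))
    fl1_resp = cfg.viable_fl1_baseline * (1.0 + ca)
    fl1 = _fill_fl(cfg, rng, t, cls, fl1_resp, np.full(len(t), cfg.viable_fl1_baseline))

    events = EventTable.from_arrays(t, fsc, fsc_h, ssc, fl1, fl4, label=labels)
    gt = GroundTruth(
        protocol="em",
        seed=int(cfg.seed if seed is None else seed),
        truth={"resting_em_mV": float(true_em_mV), "targets_mV": [float(x) for x in targets]},
        class_counts=_class_counts(labels),
        generating_model={
            "slope_au_per_mV": cfg.em_slope,
            "intercept_au": cfg.em_intercept,
            "tau_s": cfg.em_tau_s,
            "responder_fraction": cfg.responder_fraction,
            "noise_cv": cfg.noise_cv,
        },
    )
    return events, gt


def simulate_ph_run(
    cfg: SimConfig,
    true_phi: float,
    schedule_htf: StimulusSchedule | None = None,
    schedule_cal: StimulusSchedule | None = None,
    nh4cl_delta: float = 0.56,
    seed: int | None = None,
) -> tuple[EventTable, EventTable, GroundTruth]:
    """One pHi determination: physiological (HTF) plus calibration aliquot.

    The HTF aliquot holds ``true_phi`` through the baseline and
    alkalinizes by ``nh4cl_delta`` units after the NH₄Cl control pulse.
    The calibration aliquot starts pH-clamped at 6.0 and tracks the
    KOH ladder; BCECF fluorescence follows the log-linear generating
    model in both.
    """
    if not 6.0 <= true_phi <= 8.0:
        raise ValueError(f"true pHi {true_phi} outside the calibrated range [6, 8]")
    schedule_htf = schedule_htf or ph_htf_schedule()
    schedule_cal = schedule_cal or ph_cal_schedule()
    base_seed = cfg.seed if seed is None else seed
    seed_htf, seed_cal = _spawn_seeds(base_seed, 2)

    def bcecf(ph: np.ndarray) -> np.ndarray:
        return 10.0 ** (cfg.ph_slope * ph + cfg.ph_intercept)

    # HTF aliquot: baseline at true pHi, NH4Cl step
    rng = np.random.default_rng(seed_htf)
    t, cls, fsc, fsc_h, ssc, labels = _base_events(cfg, rng, schedule_htf.duration_s)
    nh4 = schedule_htf.find("NH4Cl")
    ph_t = _interp(
        t,
        *_on_grid(
            schedule_htf.duration_s,
            lambda g: _relaxation(g, [nh4.time_s], [true_phi + nh4cl_delta], true_phi, 10.0),
        ),
    )
    fl1 = _fill_fl(cfg, rng, t, cls, bcecf(ph_t), bcecf(np.full_like(t, true_phi)))
    fl4 = cfg.background_fl_median * _noise(rng, cfg.noise_cv, len(t))
    htf = EventTable.from_arrays(t, fsc, fsc_h, ssc, fl1, fl4, label=labels)

    # H⁺Cal aliquot: pH clamped to the KOH ladder
    rng = np.random.default_rng(seed_cal)
    t, cls, fsc, fsc_h, ssc, labels_cal = _base_events(cfg, rng, schedule_cal.duration_s)
    times = [a.time_s for a in schedule_cal.additions]
    targets = [a.target for a in schedule_cal.additions]
    ph_t = _interp(
        t,
        *_on_grid(
            schedule_cal.duration_s,
            lambda g: _relaxation(g, times, targets, 6.0, cfg.ph_tau_s),
        ),
    )
    fl1 = _fill_fl(cfg, rng, t, cls, bcecf(ph_t), bcecf(np.full_like(t, 6.0)))
    fl4 = cfg.background_fl_median * _noise(rng, cfg.noise_cv, len(t))
    cal = EventTable.from_arrays(t, fsc, fsc_h, ssc, fl1, fl4, label=labels_cal)

    gt = GroundTruth(
        protocol="ph",
        seed=int(base_seed),
        truth={
            "phi": float(true_phi),
            "nh4cl_delta": float(nh4cl_delta),
            "ladder_phe": [float(x) for x in targets],
        },
        class_counts={"htf": _class_counts(labels), "cal": _class_counts(labels_cal)},
        generating_model={
            "log10F_slope_per_pH": cfg.ph_slope,
            "log10F_intercept": cfg.ph_intercept,
            "tau_s": cfg.ph_tau_s,
            "responder_fraction": cfg.responder_fraction,
            "noise_cv": cfg.noise_cv,
        },
    )
    return htf, cal, gt


def simulate_ca_run(
    cfg: SimConfig,
    peak_nc: float,
    peak_cap: float,
    schedule: StimulusSchedule | None = None,
    seed: int | None = None,
) -> tuple[EventTable, EventTable, GroundTruth]:
    """Paired NC/CAP progesterone-response recordings.

    Generating traces are built on the normalized scale (baseline 0,
    transient to the stated peak, ionomycin maximum, Mn²⁺ quench) and
    mapped to raw fl1 through F = F₀·(1 + trace).
    """
    if peak_nc < 0 or peak_cap < 0:
        raise ValueError("peak amplitudes must be >= 0")
    schedule = schedule or ca_schedule()
    base_seed = cfg.seed if seed is None else seed
    seeds = _spawn_seeds(base_seed, 2)
    tables = []
    counts = {}
    for condition, peak, s in zip(("nc", "cap"), (peak_nc, peak_cap), seeds):
        rng = np.random.default_rng(s)
        t, cls, fsc, fsc_h, ssc, labels = _base_events(cfg, rng, schedule.duration_s)
        trace = _interp(
            t, *_on_grid(schedule.duration_s, lambda g: _ca_trace(g, schedule, peak, cfg))
        )
        # the generating trace is the whole viable population's median
        # response: progesterone acts on every intact cell, so there is
        # no separate non-responder class in this protocol
        f_resp = cfg.viable_fl1_baseline * (1.0 + trace)
        fl1 = _fill_fl(cfg, rng, t, cls, f_resp, f_resp)
        fl4 = cfg.background_fl_median * _noise(rng, cfg.noise_cv, len(t))
        tables.append(EventTable.from_arrays(t, fsc, fsc_h, ssc, fl1, fl4, label=labels))
        counts[condition] = _class_counts(labels)
    gt = GroundTruth(
        protocol="ca",
        seed=int(base_seed),
        truth={"peak_nc": float(peak_nc), "peak_cap": float(peak_cap)},
        class_counts=counts,
        generating_model={
            "tau_rise_s": cfg.ca_tau_rise_s,
            "tau_decay_s": cfg.ca_tau_decay_s,
            "plateau_fraction": cfg.ca_plateau_fraction,
            "iono_max": cfg.ca_iono_max,
            "mn_min": cfg.ca_mn_min,
            "responder_fraction": cfg.responder_fraction,
            "noise_cv": cfg.noise_cv,
        },
    )
    return tables[0], tables[1], gt
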