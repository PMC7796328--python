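"""End-to-end protocol runners for the three capacitation parameters.

Each runner composes the pipeline stages — gate, trace, plateau/peak,
calibrate, classify — over a paired NC/CAP sample and emits a
:class:`SampleResult` with the values, the delta, the classification
category and a QC block.  QC failures (poor calibration fit, collapsed
gates, failed NH₄Cl control) mark the result ``flagged`` without
suppressing the numbers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import calcium_response as ca
from . import em_calibration as em
from . import ph_calibration as ph
from .fcs_io import EventTable
from .gating import GateConfig, apply_gates
from .kinetics import (
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
from .cohort_stats import CohortSummary, delta_vs_zero, paired_compare, summarize_cohort

__all__ = [
    "SampleResult",
    "ProtocolError",
    "estimate_em",
    "estimate_ph",
    "estimate_ca",
    "run_em_protocol",
    "run_ph_protocol",
    "run_ca_protocol",
    "run_cohort",
    "RESULT_SCHEMA_VERSION",
    "MIN_GATE_RETENTION",
]

RESULT_SCHEMA_VERSION = 1
#: total gate retention below this flags the sample
MIN_GATE_RETENTION = 0.10

DONOR_CLASSES = ("known_paternity", "no_known_paternity", "unspecified")


class ProtocolError(ValueError):
    pass


@dataclass
class SampleResult:
    """Per-sample outcome of one protocol over an NC/CAP pair."""

    sample_id: str
    donor_class: str
    parameter: str  # "Em" | "pHi" | "Ca"
    nc_value: float
    cap_value: float
    delta: float
    category: str
    qc: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    flagged: bool = False
    schema_version: int = RESULT_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.donor_class not in DONOR_CLASSES:
            raise ValueError(
                f"donor_class must be one of {DONOR_CLASSES}, got {self.donor_class!r}"
            )
        if np.isfinite(self.nc_value) and np.isfinite(self.cap_value):
            expected = self.cap_value - self.nc_value
            if abs(self.delta - expected) > 1e-9:
                raise ValueError("delta must equal cap_value - nc_value")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "SampleResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("schema_version", None)
        return cls(schema_version=RESULT_SCHEMA_VERSION, **payload)


# ---------------------------------------------------------------------------
# per-condition estimators


def estimate_em(
    events: EventTable,
    schedule: StimulusSchedule | None = None,
    gates: GateConfig | None = None,
    temperature_K: float = em.DEFAULT_TEMPERATURE_K,
    k_in_mM: float = em.DEFAULT_K_IN_MM,
) -> dict:
    """Absolute resting Em (mV) from one voltage-dye recording.

    Gate, read the resting-state plateau, read the responding-population
    plateau after each K⁺ step, fit fluorescence against the Nernst
    targets, and invert the fit at the resting fluorescence.
    """
    schedule = schedule or em_schedule()
    gates = gates or GateConfig()
    gated, retention = apply_gates(events, gates)
    if retention["total"] < MIN_GATE_RETENTION or len(gated) == 0:
        raise ProtocolError(
            f"gates retained {100 * retention['total']:.1f}% of events; "
            "recording unusable"
        )
    resting_f = plateau_median(
        gated, "fl4_a", PlateauWindow(schedule.baseline_s - 30.0, schedule.baseline_s, "resting")
    )
    points = []
    for addition, window in zip(schedule.additions, plateau_windows(schedule)):
        if addition.target is None:
            continue
        target_mV = em.nernst_em(addition.target, k_in_mM, temperature_K)
        median_f = plateau_median(
            gated, "fl4_a", window, subpop="responding", reference=resting_f
        )
        points.append((target_mV, median_f))
    fit = em.fit_em_calibration(points)
    value = em.interpolate_em(fit, resting_f)
    return {
        "em_mV": value,
        "fit": fit,
        "resting_fluorescence": resting_f,
        "retention": retention,
    }


def estimate_ph(
    htf_events: EventTable,
    cal_events: EventTable,
    schedule_htf: StimulusSchedule | None = None,
    schedule_cal: StimulusSchedule | None = None,
    gates: GateConfig | None = None,
) -> dict:
    """Absolute pHi from one HTF recording and its own calibration aliquot.

    The titration fit uses the clamped baseline (pHe 6.0) plus the
    plateau after each KOH step; the sample's pHi is the fit inverted at
    its baseline fluorescence, and the NH₄Cl pulse must raise the
    calibrated pH for the responsiveness control to pass.
    """
    schedule_htf = schedule_htf or ph_htf_schedule()
    schedule_cal = schedule_cal or ph_cal_schedule()
    gates = gates or GateConfig()

    cal_gated, cal_retention = apply_gates(cal_events, gates)
    htf_gated, htf_retention = apply_gates(htf_events, gates)
    for name, retention in (("calibration", cal_retention), ("HTF", htf_retention)):
        if retention["total"] < MIN_GATE_RETENTION:
            raise ProtocolError(f"{name} recording: gates retained below the floor")

    base_window = PlateauWindow(schedule_cal.baseline_s - 30.0, schedule_cal.baseline_s, "pHe 6.0")
    base_f = plateau_median(cal_gated, "fl1_a", base_window)
    points = [(6.0, base_f)]
    for addition, window in zip(schedule_cal.additions, plateau_windows(schedule_cal)):
        median_f = plateau_median(
            cal_gated, "fl1_a", window, subpop="responding", reference=base_f
        )
        points.append((addition.target, median_f))
    fit = ph.fit_ph_calibration(points)

    htf_base = PlateauWindow(schedule_htf.baseline_s - 30.0, schedule_htf.baseline_s, "baseline")
    sample_f = plateau_median(htf_gated, "fl1_a", htf_base)
    phi = ph.interpolate_ph(fit, sample_f)

    trace = bin_median_trace(htf_gated, "fl1_a", duration_s=schedule_htf.duration_s)
    control = ph.nh4cl_responsiveness(trace, schedule_htf, fit)
    return {
        "phi": phi,
        "fit": fit,
        "nh4cl": control,
        "retention": {"htf": htf_retention, "cal": cal_retention},
    }


def estimate_ca(
    events: EventTable,
    schedule: StimulusSchedule | None = None,
    gates: GateConfig | None = None,
) -> dict:
    """Normalized progesterone peak (F_Peak) from one Fluo3 recording."""
    schedule = schedule or ca_schedule()
    gates = gates or GateConfig()
    gated, retention = apply_gates(events, gates)
    if retention["total"] < MIN_GATE_RETENTION or len(gated) == 0:
        raise ProtocolError("gates retained below the floor; recording unusable")
    trace = bin_median_trace(gated, "fl1_a", duration_s=schedule.duration_s)
    normalized = normalize_trace(trace, schedule.baseline_window())
    additions = {a.compound: a.time_s for a in schedule.additions}
    pg_window = PlateauWindow(additions["progesterone"], additions["ionomycin"], "progesterone")
    f_peak = ca.extract_fpeak(normalized, pg_window)
    qc = ca.dynamic_range_qc(
        normalized,
        f_peak,
        PlateauWindow(additions["ionomycin"], additions["MnCl2"], "ionomycin"),
        PlateauWindow(additions["MnCl2"], schedule.duration_s, "MnCl2"),
    )
    return {"f_peak": f_peak, "qc": qc, "retention": retention}


# ---------------------------------------------------------------------------
# paired protocol runners


def _fit_qc(fit) -> dict:
    return {"slope": fit.slope, "intercept": fit.intercept, "r_squared": fit.r_squared,
            "p_value": fit.p_value, "points": fit.points}


def run_em_protocol(
    nc_events: EventTable,
    cap_events: EventTable,
    sample_id: str = "sample",
    donor_class: str = "unspecified",
    schedule: StimulusSchedule | None = None,
    gates: GateConfig | None = None,
    threshold_mV: float = em.DELTA_EM_THRESHOLD_MV,
    provenance: dict | None = None,
) -> SampleResult:
    nc = estimate_em(nc_events, schedule, gates)
    cap = estimate_em(cap_events, schedule, gates)
    flagged = min(nc["retention"]["total"], cap["retention"]["total"]) < MIN_GATE_RETENTION
    return SampleResult(
        sample_id=sample_id,
        donor_class=donor_class,
        parameter="Em",
        nc_value=nc["em_mV"],
        cap_value=cap["em_mV"],
        delta=cap["em_mV"] - nc["em_mV"],
        category=em.classify_delta_em(nc["em_mV"], cap["em_mV"], threshold_mV),
        qc={
            "fit_nc": _fit_qc(nc["fit"]),
            "fit_cap": _fit_qc(cap["fit"]),
            "retention_nc": nc["retention"],
            "retention_cap": cap["retention"],
        },
        provenance=provenance or {},
        flagged=flagged,
    )


def run_ph_protocol(
    nc_htf: EventTable,
    nc_cal: EventTable,
    cap_htf: EventTable,
    cap_cal: EventTable,
    sample_id: str = "sample",
    donor_class: str = "unspecified",
    gates: GateConfig | None = None,
    threshold: float = ph.DELTA_PH_THRESHOLD,
    provenance: dict | None = None,
) -> SampleResult:
    """Two-aliquot design: each condition is calibrated against its own
    H⁺Cal recording."""
    nc = estimate_ph(nc_htf, nc_cal, gates=gates)
    cap = estimate_ph(cap_htf, cap_cal, gates=gates)
    flagged = not (nc["nh4cl"].passed and cap["nh4cl"].passed)
    return SampleResult(
        sample_id=sample_id,
        donor_class=donor_class,
        parameter="pHi",
        nc_value=nc["phi"],
        cap_value=cap["phi"],
        delta=cap["phi"] - nc["phi"],
        category=ph.classify_delta_ph(nc["phi"], cap["phi"], threshold),
        qc={
            "fit_nc": _fit_qc(nc["fit"]),
            "fit_cap": _fit_qc(cap["fit"]),
            "nh4cl_nc": asdict(nc["nh4cl"]),
            "nh4cl_cap": asdict(cap["nh4cl"]),
            "retention_nc": nc["retention"],
            "retention_cap": cap["retention"],
        },
        provenance=provenance or {},
        flagged=flagged,
    )


def run_ca_protocol(
    nc_events: EventTable,
    cap_events: EventTable,
    sample_id: str = "sample",
    donor_class: str = "unspecified",
    schedule: StimulusSchedule | None = None,
    gates: GateConfig | None = None,
    threshold: float = ca.DELTA_FPEAK_THRESHOLD,
    provenance: dict | None = None,
) -> SampleResult:
    nc = estimate_ca(nc_events, schedule, gates)
    cap = estimate_ca(cap_events, schedule, gates)
    flagged = not (nc["qc"].passed and cap["qc"].passed)
    return SampleResult(
        sample_id=sample_id,
        donor_class=donor_class,
        parameter="Ca",
        nc_value=nc["f_peak"],
        cap_value=cap["f_peak"],
        delta=cap["f_peak"] - nc["f_peak"],
        category=ca.classify_delta_fpeak(nc["f_peak"], cap["f_peak"], threshold),
        qc={
            "qc_nc": asdict(nc["qc"]),
            "qc_cap": asdict(cap["qc"]),
            "retention_nc": nc["retention"],
            "retention_cap": cap["retention"],
        },
        provenance=provenance or {},
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# cohort aggregation


def run_cohort(results: list[SampleResult]) -> dict:
    """Category distributions and paired tests per donor class.

    All results must share one parameter (mixing Em with pHi in one
    summary is an error); each donor class needs at least three samples.
    """
    if not results:
        raise ProtocolError("no results to summarize")
    parameters = {r.parameter for r in results}
    if len(parameters) > 1:
        raise ProtocolError(f"mixed parameters in one cohort summary: {sorted(parameters)}")
    parameter = parameters.pop()
    by_class: dict[str, list[SampleResult]] = {}
    for r in results:
        by_class.setdefault(r.donor_class, []).append(r)
    out: dict[str, dict] = {"parameter": parameter, "classes": {}}
    for donor_class, rs in by_class.items():
        if len(rs) < 3:
            raise ProtocolError(
                f"donor class {donor_class!r} has {len(rs)} samples; >= 3 required"
            )
        nc = [r.nc_value for r in rs]
        cap = [r.cap_value for r in rs]
        deltas = [r.delta for r in rs]
        summary: CohortSummary = summarize_cohort([r.category for r in rs], donor_class)
        out["classes"][donor_class] = {
            "summary": summary,
            "paired": paired_compare(nc, cap),
            "delta_vs_zero": delta_vs_zero(deltas),
        }
    return out
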