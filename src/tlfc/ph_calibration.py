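"""Absolute intracellular pH from BCECF fluorescence.

Nigericin in high-K⁺ calibration medium (H⁺Cal: 120 mM KCl, 25 mM
HEPES, 1 mM MgCl₂, 10 µM nigericin, pH 6.0) collapses the transmembrane
H⁺ gradient, locking pHi to pHe.  Stepwise KOH additions — sized by the
Henderson–Hasselbalch equation for the HEPES buffer — raise pHe by 0.25
units per step up to 8.0, tracing out a log-linear fluorescence-vs-pH
calibration.  Inverting the fit at a sample's median fluorescence
yields its absolute pHi; an NH₄Cl pulse serves as a responsiveness
control.  Capacitation-associated change is classified from
ΔpHi = pHi_CAP − pHi_NC against a ±0.1 unit threshold.

The calibration is linear in log₁₀(fluorescence) versus pHe.  Either
slope sign is accepted and reported: BCECF photophysics predicts a
positive slope, but the fit does not presume an axis convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .em_calibration import CalibrationError, _ols_line
from .kinetics import KineticTrace, PlateauWindow, StimulusSchedule

__all__ = [
    "PhCalibrationFit",
    "PhResult",
    "ResponsivenessCheck",
    "hh_base_fraction",
    "koh_addition_amount",
    "koh_titration_schedule",
    "fit_ph_calibration",
    "interpolate_ph",
    "classify_delta_ph",
    "nh4cl_responsiveness",
    "HEPES_PKA_20C",
    "DELTA_PH_THRESHOLD",
]

#: HEPES pKa at 20 °C, used to size the KOH steps
HEPES_PKA_20C = 7.55
#: |ΔpHi| classification threshold; boundary ties map to "unchanged"
DELTA_PH_THRESHOLD = 0.1
#: H⁺Cal HEPES concentration (mM)
HCAL_HEPES_MM = 25.0


@dataclass
class PhCalibrationFit:
    """OLS fit log₁₀(F) = slope·pHe + intercept over the titration plateaus."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    points: list[tuple[float, float]]  # (pHe, median fluorescence a.u.)

    @property
    def ph_range(self) -> tuple[float, float]:
        ph = [p[0] for p in self.points]
        return min(ph), max(ph)

    def predict(self, ph: float) -> float:
        """Fluorescence expected at a given pH (inverse of interpolation)."""
        return 10 ** (self.slope * ph + self.intercept)


@dataclass
class PhResult:
    ph_nc: float
    ph_cap: float

    @property
    def delta(self) -> float:
        return self.ph_cap - self.ph_nc

    @property
    def category(self) -> str:
        return classify_delta_ph(self.ph_nc, self.ph_cap)


class KohStep(NamedTuple):
    ph_from: float
    ph_to: float
    amount_umol: float
    volume_uL: float | None


def hh_base_fraction(ph: float, pka: float = HEPES_PKA_20C) -> float:
    """Deprotonated (base) fraction of a buffer at a given pH.

    Henderson–Hasselbalch in fractional form: 1/(1 + 10^(pKa − pH)).
    Strictly increasing in pH with range (0, 1), and symmetric about
    the half-titration point f(pKa) = 0.5.
    """
    ph, pka = float(ph), float(pka)
    if not (np.isfinite(ph) and np.isfinite(pka)):
        raise ValueError("pH and pKa must be finite")
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def koh_addition_amount(
    buffer_mM: float,
    volume_mL: float,
    ph_from: float,
    ph_to: float,
    pka: float = HEPES_PKA_20C,
    stock_mM: float | None = None,
) -> KohStep:
    """Strong base (µmol) needed to raise a buffered bath by one pH step.

    Each mole of KOH deprotonates one mole of HEPES, so
    amount = [buffer]·V·(f(pH_to) − f(pH_from)) with f the base
    fraction.  When a stock concentration is given the dispensed volume
    (µL) is reported too; the stock is otherwise assumed concentrated
    enough for dilution to be negligible.
    """
    if buffer_mM <= 0 or volume_mL <= 0:
        raise ValueError("buffer concentration and volume must be positive")
    if ph_to < ph_from:
        raise ValueError("ph_to must be >= ph_from (strong base only raises pH)")
    amount = buffer_mM * volume_mL * (hh_base_fraction(ph_to, pka) - hh_base_fraction(ph_from, pka))
    volume_uL = None
    if stock_mM is not None:
        if stock_mM <= 0:
            raise ValueError("stock concentration must be positive")
        volume_uL = amount / (stock_mM / 1e3)  # µmol / (µmol/µL)
    return KohStep(ph_from, ph_to, amount, volume_uL)


def koh_titration_schedule(
    buffer_mM: float = HCAL_HEPES_MM,
    volume_mL: float = 1.0,
    ph_start: float = 6.0,
    ph_stop: float = 8.0,
    step: float = 0.25,
    pka: float = HEPES_PKA_20C,
    stock_mM: float | None = None,
) -> list[KohStep]:
    """Per-step KOH amounts for the full titration ladder.

    The default 6.0 → 8.0 ladder in 0.25-unit steps yields eight
    additions whose amounts telescope: their sum equals the closed-form
    total [buffer]·V·(f(8.0) − f(6.0)).
    """
    if not ph_stop > ph_start:
        raise ValueError("ph_stop must exceed ph_start")
    n = int(round((ph_stop - ph_start) / step))
    if abs(ph_start + n * step - ph_stop) > 1e-9:
        raise ValueError("ladder does not divide evenly into steps")
    return [
        koh_addition_amount(
            buffer_mM,
            volume_mL,
            ph_start + k * step,
            ph_start + (k + 1) * step,
            pka,
            stock_mM,
        )
        for k in range(n)
    ]


def fit_ph_calibration(points, r2_min: float = 0.9) -> PhCalibrationFit:
    """OLS on log₁₀(median F) versus pHe over the titration plateaus.

    Requires at least four points with distinct pHe; any non-positive
    fluorescence is an error (log undefined), and fits with R² below
    ``r2_min`` are refused.
    """
    pts = [(float(ph), float(f)) for ph, f in points]
    if len(pts) < 4:
        raise CalibrationError(f"need >= 4 calibration points, got {len(pts)}")
    ph = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any(f <= 0):
        raise CalibrationError("non-positive median fluorescence in calibration points")
    if np.ptp(ph) == 0:
        raise CalibrationError("calibration points are degenerate: all pHe values equal")
    slope, intercept, r2, p = _ols_line(ph, np.log10(f))
    if r2 < r2_min:
        raise CalibrationError(
            f"pH calibration fit R² = {r2:.3f} below the {r2_min} floor; "
            "re-acquire the titration recording"
        )
    return PhCalibrationFit(slope, intercept, r2, p, pts)


def interpolate_ph(fit: PhCalibrationFit, median_F: float) -> float:
    """Invert the calibration: pHi = (log₁₀F − c)/m.

    Values beyond the titrated pH range are extrapolated with a warning.
    """
    if fit.slope == 0:
        raise CalibrationError("zero calibration slope: fluorescence carries no pH information")
    if median_F <= 0:
        raise ValueError("median fluorescence must be positive")
    ph = (np.log10(median_F) - fit.intercept) / fit.slope
    lo, hi = fit.ph_range
    if not lo <= ph <= hi:
        warnings.warn(
            f"interpolated pH {ph:.2f} outside calibrated range [{lo}, {hi}]; "
            "extrapolating",
            stacklevel=2,
        )
    return float(ph)


def classify_delta_ph(
    ph_nc: float, ph_cap: float, threshold: float = DELTA_PH_THRESHOLD
) -> str:
    """Classify ΔpHi = pHi_CAP − pHi_NC against the ±threshold band.

    Above +threshold → ``alkalinized``; below −threshold →
    ``acidified``; the closed band (boundary included) → ``unchanged``.
    """
    if not (np.isfinite(ph_nc) and np.isfinite(ph_cap)):
        raise ValueError("pH values must be finite")
    delta = ph_cap - ph_nc
    if delta > threshold:
        return "alkalinized"
    if delta < -threshold:
        return "acidified"
    return "unchanged"


@dataclass
class ResponsivenessCheck:
    passed: bool
    magnitude: float  # pH units
    ph_baseline: float
    ph_post: float


def nh4cl_responsiveness(
    trace: KineticTrace,
    schedule: StimulusSchedule,
    fit: PhCalibrationFit,
    threshold: float = 0.1,
    settle_s: float = 90.0,
    width_s: float = 30.0,
) -> ResponsivenessCheck:
    """NH₄Cl control: did the cells alkalinize when challenged?

    Compares the calibrated pH of the post-NH₄Cl plateau against the
    baseline; the sample passes only when the increase strictly exceeds
    ``threshold`` pH units (an unresponsive sample invalidates its pHi
    determination).
    """
    addition = schedule.find("NH4Cl")
    if addition is None:
        raise ValueError("schedule contains no NH4Cl addition")
    baseline = PlateauWindow(0.0, addition.time_s, "baseline")
    post = PlateauWindow(
        addition.time_s + settle_s, addition.time_s + settle_s + width_s, "NH4Cl"
    )
    base_values = trace.window_values(baseline)
    post_values = trace.window_values(post)
    if len(base_values) == 0 or len(post_values) == 0:
        raise ValueError("baseline or NH4Cl window contains no valid bins")
    ph_base = interpolate_ph(fit, float(np.mean(base_values)))
    ph_post = interpolate_ph(fit, float(np.mean(post_values)))
    magnitude = ph_post - ph_base
    # strictly greater than the threshold; the 1e-9 guard keeps exact
    # boundary magnitudes on the "fail" side despite rounding
    return ResponsivenessCheck(magnitude > threshold + 1e-9, magnitude, ph_base, ph_post)
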