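"""Absolute membrane potential from voltage-dye fluorescence.

Valinomycin turns the sperm plasma membrane into a K⁺ electrode, so
each extracellular K⁺ concentration clamps the membrane at its Nernst
potential.  Plateau medians of the carbocyanine dye (disc) at the five
K⁺ steps define a linear fluorescence-vs-Em calibration; inverting the
fitted line at the resting-state fluorescence yields the absolute
resting Em.  Capacitation-associated change is classified from
ΔEm = Em_CAP − Em_NC against a ±5 mV threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants, stats

__all__ = [
    "EmCalibrationFit",
    "EmResult",
    "CalibrationError",
    "nernst_em",
    "kcl_addition_volume",
    "kcl_addition_schedule",
    "fit_em_calibration",
    "interpolate_em",
    "classify_delta_em",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_K_IN_MM",
    "DELTA_EM_THRESHOLD_MV",
]

#: acquisitions are run at room temperature (20 °C)
DEFAULT_TEMPERATURE_K = 293.15
#: assumed intracellular K⁺ (mM)
DEFAULT_K_IN_MM = 120.0
#: |ΔEm| classification threshold (mV); boundary ties map to "unchanged"
DELTA_EM_THRESHOLD_MV = 5.0


class CalibrationError(ValueError):
    pass


@dataclass
class EmCalibrationFit:
    """OLS fit F = slope·Em + intercept over the calibration plateaus."""

    slope: float  # a.u. per mV
    intercept: float  # a.u.
    r_squared: float
    p_value: float
    points: list[tuple[float, float]]  # (Em mV, median fluorescence a.u.)

    @property
    def fluorescence_range(self) -> tuple[float, float]:
        f = [p[1] for p in self.points]
        return min(f), max(f)

    def predict(self, em_mV: float) -> float:
        return self.slope * em_mV + self.intercept


@dataclass
class EmResult:
    em_nc_mV: float
    em_cap_mV: float

    @property
    def delta_mV(self) -> float:
        return self.em_cap_mV - self.em_nc_mV

    @property
    def category(self) -> str:
        return classify_delta_em(self.em_nc_mV, self.em_cap_mV)


def nernst_em(
    k_out_mM: float,
    k_in_mM: float = DEFAULT_K_IN_MM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """K⁺ equilibrium potential (RT/F)·ln([K⁺]out/[K⁺]in) in mV.

    Monovalent cation (z = 1).  With the 20 °C default and 120 mM
    internal K⁺ the protocol's 5/10/15/25/40 mM steps give −80.3,
    −62.8, −52.5, −39.6 and −27.7 mV.
    """
    if k_out_mM <= 0 or k_in_mM <= 0:
        raise ValueError("K⁺ concentrations must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    rt_over_f = constants.R * temperature_K / constants.value("Faraday constant")
    return 1e3 * rt_over_f * np.log(k_out_mM / k_in_mM)


def kcl_addition_volume(
    current_volume: float,
    current_K_mM: float,
    stock_K_mM: float,
    target_K_mM: float,
) -> float:
    """Stock volume needed to raise the bath K⁺ to a target concentration.

    Solves the mass balance (C₀·V + C_s·x)/(V + x) = C_t for x, in the
    same units as ``current_volume``.
    """
    if current_K_mM < 0:
        raise ValueError("current concentration must be >= 0")
    if target_K_mM < current_K_mM:
        raise ValueError("target concentration below current; KCl cannot be removed")
    if target_K_mM >= stock_K_mM:
        raise CalibrationError(
            f"target {target_K_mM} mM not reachable from a {stock_K_mM} mM stock"
        )
    return current_volume * (target_K_mM - current_K_mM) / (stock_K_mM - target_K_mM)


def kcl_addition_schedule(
    initial_volume: float,
    initial_K_mM: float,
    stock_K_mM: float,
    targets_mM,
) -> list[dict[str, float]]:
    """Sequential addition volumes accounting for cumulative dilution.

    Each step updates the bath volume, so later additions are computed
    against the diluted state, not the starting conditions.
    """
    volume, conc = float(initial_volume), float(initial_K_mM)
    steps = []
    for target in targets_mM:
        x = kcl_addition_volume(volume, conc, stock_K_mM, target)
        volume += x
        conc = float(target)
        steps.append({"target_mM": conc, "volume_added": x, "bath_volume": volume})
    return steps


def _ols_line(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


def fit_em_calibration(points, r2_min: float = 0.9) -> EmCalibrationFit:
    """Ordinary least squares F = a·Em + b over the calibration points.

    Requires at least three points with distinct Em values; fits with
    R² below ``r2_min`` are refused (re-acquire the calibration).
    """
    pts = [(float(em), float(f)) for em, f in points]
    if len(pts) < 3:
        raise CalibrationError(f"need >= 3 calibration points, got {len(pts)}")
    em = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.ptp(em) == 0:
        raise CalibrationError("calibration points are degenerate: all Em values equal")
    slope, intercept, r2, p = _ols_line(em, f)
    if r2 < r2_min:
        raise CalibrationError(
            f"calibration fit R² = {r2:.3f} below the {r2_min} floor; "
            "re-acquire the calibration recording"
        )
    return EmCalibrationFit(slope, intercept, r2, p, pts)


def interpolate_em(fit: EmCalibrationFit, median_F: float) -> float:
    """Invert the calibration line: Em = (F − b)/a, in mV.

    Fluorescence outside the calibrated range is extrapolated with a
    warning rather than refused.
    """
    if fit.slope == 0:
        raise CalibrationError("zero calibration slope: fluorescence carries no Em information")
    lo, hi = fit.fluorescence_range
    if not lo <= median_F <= hi:
        warnings.warn(
            f"fluorescence {median_F:g} outside calibration range [{lo:g}, {hi:g}]; "
            "extrapolating",
            stacklevel=2,
        )
    return (median_F - fit.intercept) / fit.slope


def classify_delta_em(
    em_nc_mV: float, em_cap_mV: float, threshold_mV: float = DELTA_EM_THRESHOLD_MV
) -> str:
    """Classify ΔEm = Em_CAP − Em_NC against the ±threshold band.

    More negative than −threshold → ``hyperpolarized``; more positive
    than +threshold → ``depolarized``; the closed band (boundary
    included) → ``unchanged``.
    """
    if not (np.isfinite(em_nc_mV) and np.isfinite(em_cap_mV)):
        raise ValueError("membrane potentials must be finite")
    delta = em_cap_mV - em_nc_mV
    if delta < -threshold_mV:
        return "hyperpolarized"
    if delta > threshold_mV:
        return "depolarized"
    return "unchanged"
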