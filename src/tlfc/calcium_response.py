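"""Progesterone-induced calcium responses on normalized Fluo3 traces.

Progesterone opens the sperm-specific CatSper channel, producing a fast
calcium transient followed by a sustained plateau.  The analysis is
deliberately qualitative: traces are normalized to (F − F₀)/F₀ and the
peak of the normalized trace after the progesterone addition (F_Peak)
is compared between non-capacitating and capacitating conditions.  No
absolute calcium concentration is computed — the ionomycin maximum and
Mn²⁺-quench minimum only bound the indicator's dynamic range as QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import KineticTrace, PlateauWindow

__all__ = [
    "CaQC",
    "CaResult",
    "extract_fpeak",
    "dynamic_range_qc",
    "classify_delta_fpeak",
    "DELTA_FPEAK_THRESHOLD",
    "PG_WINDOW",
    "IONO_WINDOW",
    "MN_WINDOW",
]

#: |ΔF_Peak| classification threshold; boundary ties map to "unchanged"
DELTA_FPEAK_THRESHOLD = 0.25
#: default protocol windows (s): Pg at 120, ionomycin at 300, MnCl₂ at 540
PG_WINDOW = PlateauWindow(120.0, 300.0, "progesterone")
IONO_WINDOW = PlateauWindow(300.0, 540.0, "ionomycin")
MN_WINDOW = PlateauWindow(540.0, 600.0, "MnCl2")


def extract_fpeak(normalized_trace: KineticTrace, pg_window: PlateauWindow = PG_WINDOW) -> float:
    """Peak of the normalized trace within the progesterone window.

    The maximum is read from bin medians, not single events, so it
    reflects the population response rather than outlier cells.
    """
    if not normalized_trace.normalized:
        raise ValueError("extract_fpeak requires a normalized trace (baseline at 0)")
    values = normalized_trace.window_values(pg_window)
    if len(values) == 0:
        raise ValueError("progesterone window contains no valid bins")
    return float(np.max(values))


@dataclass
class CaQC:
    """Dynamic-range sanity record (not an exception: QC travels with the result)."""

    iono_max: float
    mn_min: float
    f_peak: float
    ordering_ok: bool  # Mn²⁺ min < baseline 0 < ionomycin max
    f_peak_ok: bool  # F_Peak does not exceed the ionomycin maximum

    @property
    def passed(self) -> bool:
        return self.ordering_ok and self.f_peak_ok


def dynamic_range_qc(
    normalized_trace: KineticTrace,
    f_peak: float,
    iono_window: PlateauWindow = IONO_WINDOW,
    mn_window: PlateauWindow = MN_WINDOW,
) -> CaQC:
    """Check the indicator's dynamic range brackets the response.

    Ionomycin saturates the indicator (max over its window) and Mn²⁺
    quenches it (min over its window); a valid recording has
    min < 0 < max on the normalized scale and F_Peak at or below the
    ionomycin maximum.
    """
    iono = normalized_trace.window_values(iono_window)
    mn = normalized_trace.window_values(mn_window)
    if len(iono) == 0 or len(mn) == 0:
        raise ValueError("ionomycin or Mn²⁺ window contains no valid bins")
    iono_max = float(np.max(iono))
    mn_min = float(np.min(mn))
    return CaQC(
        iono_max=iono_max,
        mn_min=mn_min,
        f_peak=f_peak,
        ordering_ok=(mn_min < 0.0 < iono_max),
        f_peak_ok=(f_peak <= iono_max),
    )


def classify_delta_fpeak(
    f_peak_nc: float, f_peak_cap: float, threshold: float = DELTA_FPEAK_THRESHOLD
) -> str:
    """Classify ΔF_Peak = F_Peak_CAP − F_Peak_NC against the ±threshold band.

    Above +threshold → ``increased``; below −threshold → ``decreased``;
    the closed band (boundary included) → ``unchanged``.
    """
    if not (np.isfinite(f_peak_nc) and np.isfinite(f_peak_cap)):
        raise ValueError("F_Peak values must be finite")
    delta = f_peak_cap - f_peak_nc
    if delta > threshold:
        return "increased"
    if delta < -threshold:
        return "decreased"
    return "unchanged"


@dataclass
class CaResult:
    f_peak_nc: float
    f_peak_cap: float
    qc_nc: CaQC | None = None
    qc_cap: CaQC | None = None

    @property
    def delta(self) -> float:
        return self.f_peak_cap - self.f_peak_nc

    @property
    def category(self) -> str:
        return classify_delta_fpeak(self.f_peak_nc, self.f_peak_cap)
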