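"""Selection of viable single sperm cells from raw event streams.

Three sequential filters mirror the standard cytometry workflow:

1. debris exclusion — FSC/SSC lower thresholds;
2. aggregate (doublet) exclusion — pulse-geometry gate on the
   FSC-H/FSC-A ratio (doublets have roughly doubled area but
   sub-additive height, pushing the ratio low);
3. viability — minimum green-fluorescence intensity: Fluo3/BCECF are
   retained only by intact cells, so dead cells form a dimmer mode that
   a threshold separates from the viable mode.

Where an operator would draw these gates on density plots, this module
makes them explicit numeric parameters, with an automatic valley-finding
option for the viability threshold so analyses are reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .fcs_io import EventTable

__all__ = [
    "GateConfig",
    "GatingError",
    "apply_debris_gate",
    "apply_singlet_gate",
    "apply_viability_gate",
    "auto_viability_threshold",
    "apply_gates",
    "log_intensity_valley",
]

log = logging.getLogger(__name__)


class GatingError(ValueError):
    pass


@dataclass
class GateConfig:
    """Numeric gate positions.

    Defaults are conventions for the simulator's intensity scales (the
    source protocol sets gates manually on density plots and publishes
    no numbers); override per instrument.

    fsc_min, ssc_min
        Debris thresholds in scatter a.u.
    singlet_band
        Allowed ``fsc_h/fsc_a`` interval for single cells.
    viability_threshold
        Minimum fl1 intensity (a.u.), or ``"auto"`` to derive it from a
        heat-killed reference via :func:`auto_viability_threshold`.
    """

    fsc_min: float = 2e4
    ssc_min: float = 5e3
    singlet_band: tuple[float, float] = (0.75, 1.05)
    viability_threshold: float | str = 1e3

    def __post_init__(self) -> None:
        if self.fsc_min < 0 or self.ssc_min < 0:
            raise ValueError("debris thresholds must be >= 0")
        lo, hi = self.singlet_band
        if not lo < hi:
            raise ValueError("singlet_band lower bound must be < upper bound")
        if isinstance(self.viability_threshold, str):
            if self.viability_threshold != "auto":
                raise ValueError("viability_threshold must be a number or 'auto'")
        elif self.viability_threshold < 0:
            raise ValueError("viability_threshold must be >= 0")


def _checked(events: EventTable, kept: np.ndarray, gate: str) -> EventTable:
    out = events.select(kept)
    frac = len(out) / len(events)
    log.info("%s gate retained %.1f%% (%d/%d)", gate, 100 * frac, len(out), len(events))
    if len(out) == 0:
        warnings.warn(f"{gate} gate removed every event", stacklevel=3)
    return out


def apply_debris_gate(events: EventTable, cfg: GateConfig) -> EventTable:
    """Keep events with ``fsc_a >= fsc_min`` and ``ssc_a >= ssc_min``."""
    if len(events) == 0:
        raise GatingError("debris gate refused: empty input")
    kept = (events["fsc_a"] >= cfg.fsc_min) & (events["ssc_a"] >= cfg.ssc_min)
    return _checked(events, kept, "debris")


def apply_singlet_gate(events: EventTable, cfg: GateConfig) -> EventTable:
    """Keep events whose ``fsc_h/fsc_a`` ratio lies inside the singlet band."""
    if len(events) == 0:
        raise GatingError("singlet gate refused: empty input")
    fsc_a = events["fsc_a"]
    if np.any(fsc_a <= 0):
        raise GatingError("singlet gate requires fsc_a > 0; run the debris gate first")
    ratio = events["fsc_h"] / fsc_a
    lo, hi = cfg.singlet_band
    return _checked(events, (ratio >= lo) & (ratio <= hi), "singlet")


def apply_viability_gate(
    events: EventTable, cfg: GateConfig, killed: EventTable | None = None
) -> EventTable:
    """Keep events with fl1 at or above the viability threshold.

    With ``viability_threshold="auto"`` a heat-killed reference table is
    required and the threshold is placed at the histogram valley between
    the killed and viable fl1 modes.
    """
    if len(events) == 0:
        raise GatingError("viability gate refused: empty input")
    thr = cfg.viability_threshold
    if thr == "auto":
        if killed is None:
            raise GatingError("viability_threshold='auto' requires a heat-killed reference")
        thr = auto_viability_threshold(events, killed)
    return _checked(events, events["fl1_a"] >= float(thr), "viability")


def apply_gates(
    events: EventTable, cfg: GateConfig, killed: EventTable | None = None
) -> tuple[EventTable, dict[str, float]]:
    """Fixed gate order debris -> singlet -> viability.

    Returns the gated table and per-gate retention fractions (QC).
    """
    retention: dict[str, float] = {}
    out = apply_debris_gate(events, cfg)
    retention["debris"] = len(out) / len(events)
    if len(out):
        n = len(out)
        out = apply_singlet_gate(out, cfg)
        retention["singlet"] = len(out) / n
    if len(out):
        n = len(out)
        out = apply_viability_gate(out, cfg, killed)
        retention["viability"] = len(out) / n
    retention["total"] = len(out) / len(events)
    return out, retention


# ---------------------------------------------------------------------------
# valley finding on log-intensity histograms


def log_intensity_valley(
    values: np.ndarray,
    bins: int = 256,
    smooth: int = 5,
    min_prominence_frac: float = 0.05,
    max_valley_ratio: float = 0.5,
    min_separation_decades: float = 0.2,
) -> float | None:
    """Locate the valley between two genuinely separated intensity modes.

    Histogram of ``log10(x + 1)`` with ``bins`` bins, smoothed by a
    ``smooth``-bin moving average.  The two highest local maxima with
    prominence of at least ``min_prominence_frac`` of the histogram peak
    are candidate modes; the minimum between them is returned (in linear
    intensity units) only when the modes are at least
    ``min_separation_decades`` apart and the valley dips below
    ``max_valley_ratio`` of the lower mode.  Otherwise the sample is
    declared unimodal (``None``) — sampling wiggles on a single mode
    must not trigger a split.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        return None
    x = np.log10(values + 1.0)
    hist, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(hist, kernel, mode="same")
    peaks, _ = find_peaks(smoothed, prominence=min_prominence_frac * smoothed.max())
    if len(peaks) < 2:
        return None
    top_two = peaks[np.argsort(smoothed[peaks])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    if centers[hi] - centers[lo] < min_separation_decades or hi - lo < 2:
        return None
    valley = lo + 1 + int(np.argmin(smoothed[lo + 1 : hi]))
    if smoothed[valley] > max_valley_ratio * min(smoothed[lo], smoothed[hi]):
        return None
    return float(10 ** centers[valley] - 1.0)


def auto_viability_threshold(
    stained: EventTable, killed: EventTable, bins: int = 256, smooth: int = 5
) -> float:
    """Derive the viability fl1 threshold from a heat-killed reference.

    Heat-killed cells fluoresce above unstained background but below
    viable cells, so the combined log-intensity histogram is bimodal.
    The threshold is the smoothed-histogram minimum between the killed
    mode and the viable mode.

    Raises
    ------
    GatingError
        When the two modes are not separable (unimodal combined
        distribution), in which case a manual threshold is needed.
    """
    if len(stained) == 0 or len(killed) == 0:
        raise GatingError("auto threshold requires non-empty stained and killed tables")
    fl1_stained = stained["fl1_a"].astype(float)
    fl1_killed = killed["fl1_a"].astype(float)
    combined = np.concatenate([fl1_stained, fl1_killed])
    x = np.log10(combined + 1.0)
    hist, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth) / smooth
    smoothed = np.convolve(hist, kernel, mode="same")

    def _mode(values: np.ndarray) -> float:
        h, _ = np.histogram(np.log10(values + 1.0), bins=edges)
        return float(centers[np.argmax(np.convolve(h, kernel, mode="same"))])

    killed_mode = _mode(fl1_killed)
    viable_mode = _mode(fl1_stained)
    if viable_mode - killed_mode < 2 * (edges[1] - edges[0]):
        raise GatingError(
            "killed and viable fl1 modes are not separable; set a manual threshold"
        )
    in_between = (centers > killed_mode) & (centers < viable_mode)
    if not np.any(in_between):
        raise GatingError(
            "no histogram bins between killed and viable modes; set a manual threshold"
        )
    idx = np.flatnonzero(in_between)
    valley = idx[np.argmin(smoothed[idx])]
    threshold = float(10 ** centers[valley] - 1.0)
    # strictly between the modes by construction of the search interval
    return threshold
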