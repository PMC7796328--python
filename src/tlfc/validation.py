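"""Parameter-recovery study: the pipeline run against its own simulator.

Real donor recordings are not redistributable, so the package's
quantitative validation is closed-loop: simulate recordings with known
ground truth at the default acquisition conditions, run the full
pipeline (gate → trace → plateau → calibrate → classify), and score the
recovered values against the truth.  One seeded replicate simulates a
paired NC/CAP sample for each protocol:

* Em pair with a capacitation-associated hyperpolarization of −11 mV,
  resting NC potential drawn per replicate from −70…−55 mV;
* pHi pair with an alkalinization of +0.36 units, NC pHi drawn from
  6.4…6.9;
* Ca pair with normalized progesterone peaks 0.88 (NC) and 1.90 (CAP).

The paired deltas mirror the magnitudes a capacitation-competent donor
shows, so classification of every replicate has a known correct answer
whose true delta exceeds twice the classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium_response import classify_delta_fpeak
from .em_calibration import classify_delta_em
from .ph_calibration import classify_delta_ph
from .protocols import estimate_ca, estimate_em, estimate_ph
from .synthetic_data import SimConfig, simulate_ca_run, simulate_em_run, simulate_ph_run

__all__ = ["RecoveryStats", "run_recovery_study", "EM_DELTA_MV", "PH_DELTA", "CA_PEAKS"]

EM_DELTA_MV = -11.0
PH_DELTA = 0.36
CA_PEAKS = (0.88, 1.90)


@dataclass
class RecoveryStats:
    """Aggregated scores over the replicates."""

    n_runs: int
    em_errors_mV: list[float] = field(default_factory=list)
    ph_errors: list[float] = field(default_factory=list)
    em_categories_correct: int = 0
    ph_categories_correct: int = 0
    ca_categories_correct: int = 0
    ca_delta_errors: list[float] = field(default_factory=list)

    @property
    def em_within_2mV_fraction(self) -> float:
        e = np.abs(self.em_errors_mV)
        return float(np.mean(e <= 2.0))

    @property
    def ph_within_005_fraction(self) -> float:
        e = np.abs(self.ph_errors)
        return float(np.mean(e <= 0.05))

    @property
    def classification_accuracy(self) -> float:
        total = 3 * self.n_runs
        correct = (
            self.em_categories_correct
            + self.ph_categories_correct
            + self.ca_categories_correct
        )
        return correct / total


def run_recovery_study(n_runs: int = 50, seed: int = 0) -> RecoveryStats:
    """Run ``n_runs`` seeded paired simulations through the full pipeline."""
    cfg = SimConfig()
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(4 * n_runs) % (2**31)
    rng = np.random.default_rng(int(child_seeds[0]))
    stats = RecoveryStats(n_runs=n_runs)
    for k in range(n_runs):
        s_em, s_ph, s_ca = (int(x) for x in child_seeds[4 * k + 1 : 4 * k + 4])

        # --- membrane potential ---------------------------------------
        em_nc_true = float(rng.uniform(-70.0, -55.0))
        em_cap_true = em_nc_true + EM_DELTA_MV
        nc_events, _ = simulate_em_run(cfg, em_nc_true, seed=s_em)
        cap_events, _ = simulate_em_run(cfg, em_cap_true, seed=s_em + 1)
        em_nc = estimate_em(nc_events)["em_mV"]
        em_cap = estimate_em(cap_events)["em_mV"]
        stats.em_errors_mV += [em_nc - em_nc_true, em_cap - em_cap_true]
        if classify_delta_em(em_nc, em_cap) == "hyperpolarized":
            stats.em_categories_correct += 1

        # --- intracellular pH -----------------------------------------
        ph_nc_true = float(rng.uniform(6.4, 6.9))
        ph_cap_true = ph_nc_true + PH_DELTA
        htf_nc, cal_nc, _ = simulate_ph_run(cfg, ph_nc_true, seed=s_ph)
        htf_cap, cal_cap, _ = simulate_ph_run(cfg, ph_cap_true, seed=s_ph + 1)
        ph_nc = estimate_ph(htf_nc, cal_nc)["phi"]
        ph_cap = estimate_ph(htf_cap, cal_cap)["phi"]
        stats.ph_errors += [ph_nc - ph_nc_true, ph_cap - ph_cap_true]
        if classify_delta_ph(ph_nc, ph_cap) == "alkalinized":
            stats.ph_categories_correct += 1

        # --- progesterone calcium response ----------------------------
        nc_events, cap_events, _ = simulate_ca_run(cfg, *CA_PEAKS, seed=s_ca)
        f_nc = estimate_ca(nc_events)["f_peak"]
        f_cap = estimate_ca(cap_events)["f_peak"]
        stats.ca_delta_errors.append((f_cap - f_nc) - (CA_PEAKS[1] - CA_PEAKS[0]))
        if classify_delta_fpeak(f_nc, f_cap) == "increased":
            stats.ca_categories_correct += 1
    return stats
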