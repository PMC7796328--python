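# Methods

This note documents the models, defaults and numerical choices behind
`tlfc`, and what the synthetic-data validation does and does not show.

## Measurement model

A time-lapse recording is a stream of independent single-cell events:
each cell crosses the laser once, so there are no per-cell
trajectories, only population statistics as a function of time. All
kinetic quantities are therefore computed from **per-bin medians**
(robust to the heavy-tailed intensity noise) over uniform time bins.
Default bin width is 2 s; at the nominal 700 events/s acquisition rate
(14 µL/min flow × 3×10⁶ cells/mL) a bin holds ≈1,400 events before
gating, which keeps the median's sampling noise near 1% while still
resolving the fast progesterone transient (rise τ ≈ 10 s). Bins with
fewer than 20 events are flagged and excluded from all statistics.

### Gating

Gates are explicit numeric parameters rather than hand-drawn regions,
in the fixed order debris → singlet → viability:

| gate | rule | default | rationale |
|---|---|---|---|
| debris | `fsc_a ≥ fsc_min` and `ssc_a ≥ ssc_min` | 2×10⁴ / 5×10³ a.u. | between the simulator's debris and cell modes; instrument-specific in practice |
| singlet | `fsc_h/fsc_a` in band | [0.75, 1.05] | conventional pulse geometry: doublets double the area but heights add sub-additively, pushing the ratio low |
| viability | `fl1 ≥ threshold` | 10³ a.u., or `auto` | Fluo3/BCECF are retained only by intact cells; `auto` places the threshold at the histogram valley between a heat-killed reference mode and the viable mode |

All intensity defaults are conventions matched to the simulator's
scales — the source protocols publish no gate coordinates — and must
be re-derived per instrument. Gates are idempotent filters; every run
records per-gate retention, and total retention below 10% disqualifies
a recording.

### Valley detection and the responding subpopulation

Both the automatic viability threshold and the responding-subpopulation
split use one deterministic detector: a 256-bin histogram of
log₁₀(intensity + 1), smoothed with a 5-bin moving average. A split is
accepted only when the two highest local maxima (prominence ≥ 5% of
the histogram peak) are ≥ 0.2 decades apart **and** the minimum between
them is below 50% of the lower mode. Without the prominence/depth/
separation guards, sampling wiggles on a unimodal window trigger
spurious splits whose kept half is biased by roughly +0.5σ — the
guards are what make the split safe to apply automatically.

In plateau windows, "responding" selection works as follows: if the
window is bimodal by the detector above, keep the component **farther
from the baseline reference** (non-responders by definition stay at
baseline); with no reference, keep the higher-intensity component.
Unimodal windows fall back to the plain median, which leaves a small
residual mixture bias (< 0.02 decades at the default 10% non-responder
fraction) that the calibration fit averages away. This replaces manual
subpopulation boxes with a reproducible rule.

### Plateau read-out

Additions are spaced 120 s apart; each plateau window is
`[t_add + 90 s, t_add + 120 s)` — the last quarter of the interval,
after ≈4.5 relaxation time constants (τ ≈ 20 s), where the residual
drift is ≈1% of the step. The resting/basal read-out uses the last
30 s of the 120-s baseline for the same reason. Plateau medians
require ≥ 200 events.

## Calibrations

**Membrane potential.** Nernst targets use T = 293.15 K (acquisitions
run at 20 °C room temperature) and [K⁺]in = 120 mM; both are exposed
parameters. The first calibration point (−80 mV) is the
post-valinomycin baseline itself: HTF medium already contains ≈5 mM K⁺
(4.68 KCl + 0.37 KH₂PO₄), so no KCl is added for it. The calibration
is an OLS line `F = a·Em + b` over ≥ 3 points; fits with R² < 0.9 are
refused rather than silently used. Interpolation outside the
calibrated fluorescence range warns but proceeds (capacitated samples
commonly sit slightly beyond the −80 mV point).

**Intracellular pH.** The model is linear in log₁₀(fluorescence)
versus pHe over the 6.0→8.0 ladder (9 points: the clamped baseline
plus eight 0.25-unit KOH steps). Either slope sign is accepted and
reported — BCECF photophysics predicts a positive slope, but the fit
does not presume an axis convention. Buffering is attributed to HEPES
only (25 mM, pKa 7.55 at 20 °C); Mg²⁺ and CO₂ chemistry are ignored,
and KOH stock dilution correction is available but off by default (no
stock concentration is assumed). Each condition (NC, CAP) is
calibrated against its own H⁺Cal aliquot. The NH₄Cl control must
raise the calibrated pH by strictly more than 0.1 units (with a 10⁻⁹
floating-point guard so exact-boundary magnitudes fail deterministically).

**Calcium.** Deliberately qualitative: no Grynkiewicz-style absolute
calibration is attempted. F_Peak is the maximum bin-median of the
normalized trace in the progesterone window [120 s, 300 s); the
ionomycin maximum and Mn²⁺ minimum are QC bounds only (a valid
recording has min < 0 < max and F_Peak ≤ max). F₀ is the **mean** of
the baseline bin medians — "average of the basal level" is read as the
arithmetic mean; using the median instead changes F₀ by ≪ 1% at the
default noise.

## Classification

Δ = CAP − NC per sample; thresholds ±5 mV (Em), ±0.1 units (pHi),
±0.25 (F_Peak). Boundary ties map to "unchanged" in all three — the
band is closed. Cohort percentages are integer, half-up rounded
(1/6 → 17%). Paired NC/CAP comparisons apply Shapiro–Wilk to the
paired differences at α = 0.05 (the differences are what the t-test
assumes normal) and route to the paired t-test or the Wilcoxon
signed-rank test; per-sample deltas are also tested against a zero
mean. All-identical differences are degenerate: p = 1 by convention,
flagged. No multiple-testing correction is applied; p-values are
reported raw, one per comparison.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the acquisition process — seeded Poisson
arrivals at 700 events/s, per-event multiplicative log-normal noise
(CV 25%, median-unbiased), event classes (80% viable, 8% dead, 7%
debris, 5% doublets), and stimulus-driven population kinetics relaxing
exponentially (τ = 20 s) toward each segment's target. The noise CV
and class fractions are conventions (no published values exist); the
responder fraction defaults to 0.9 since ionophore-mediated clamping
acts on nearly every intact cell. Doublets are summed pairs (area ×2,
height ×1.2). In the progesterone protocol the generating trace is
the *population median response* of all viable cells — the read-out is
explicitly population-level, so heterogeneity there is amplitude, not
a responder/non-responder dichotomy.

By construction the dye-response models are exactly the model classes
the calibrations assume (linear in Em; log-linear in pH). Passing
recovery tests therefore demonstrates pipeline correctness — gating,
trace statistics, fitting, inversion and classification introduce no
material bias — **not** robustness to model mismatch. Dye saturation,
bleaching, instrument drift, clogs and autocorrelated noise are not
simulated; stress configurations (e.g. zero-noise, all-responder,
fast-clamp limits) exist for exactness tests, not as defaults.

Generating-model coefficients default to representative published
calibration lines (Em: a = −10,682.4 a.u./mV, b = −264,308 a.u.) or
physically sensible ones (pH: log₁₀F = 0.5·pH + 0.5, chosen so the
dimmest calibration point stays well above the dead-cell mode).

## Validation problem sizes

The recovery study (`tlfc.validation.run_recovery_study`, also the
backbone of `scripts/acceptance.py`) runs 50 seeded replicates; each
simulates full-length paired recordings per protocol (720 s Em pairs,
360 s + 1080 s pH aliquot pairs, 600 s Ca pairs, ≈3.9 M events per
replicate) at the default conditions, with true values drawn per
replicate (Em_NC ∈ [−70, −55] mV with ΔEm = −11; pHi_NC ∈ [6.4, 6.9]
with ΔpHi = +0.36; F_Peak 0.88 → 1.90). Observed performance: all
replicates recover Em within ±0.8 mV and pHi within ±0.02, and all
NC/CAP classifications are correct.

## Known limitations

* Absolute Em and pHi inherit the calibration assumptions
  ([K⁺]in = 120 mM, complete nigericin equilibration); no independent
  electrophysiological cross-validation is possible in software.
* F_Peak read from bin medians carries a small positive selection bias
  (max over ~90 noisy bins, ≈ +0.02 at default noise) and an absolute
  accuracy floor of ≈0.05 for small peaks; classification at the
  ±0.25 threshold is unaffected.
* The FCS layer writes/reads the float list-mode subset of FCS 3.1
  only (no integer data, multi-dataset files, compensation or display
  transforms).
* Donor-class labels (known/no-known paternity) are user-supplied
  metadata; nothing in the data distinguishes them.
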