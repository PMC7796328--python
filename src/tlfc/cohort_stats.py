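"""Paired NC-vs-CAP statistics and cohort category summaries.

Per-sample values are paired by donor (the same ejaculate split into
non-capacitating and capacitating incubations).  The paired comparison
follows a normality gate: Shapiro–Wilk on the paired differences at
α = 0.05 selects either the paired t-test or the Wilcoxon signed-rank
test.  Per-sample deltas are additionally tested against a theoretical
mean of zero.  Cohort summaries count classification categories per
donor class and report integer percentages (half-up rounding, so
1/6 → 17%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedTestReport",
    "OneSampleReport",
    "CohortSummary",
    "paired_compare",
    "delta_vs_zero",
    "summarize_cohort",
    "SHAPIRO_ALPHA",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class PairedTestReport:
    test: str  # "paired t" | "wilcoxon signed-rank" | "degenerate"
    statistic: float
    p_value: float
    n: int
    mean_nc: float
    sem_nc: float
    mean_cap: float
    sem_cap: float
    mean_diff: float
    sem_diff: float
    shapiro_p: float
    degenerate: bool = False


@dataclass
class OneSampleReport:
    statistic: float
    p_value: float
    n: int
    mean: float
    sem: float
    degenerate: bool = False


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def paired_compare(nc_values, cap_values) -> PairedTestReport:
    """Paired NC-vs-CAP comparison with a Shapiro–Wilk normality gate.

    Differences (CAP − NC) passing Shapiro–Wilk at α = 0.05 are tested
    with the paired t-test, otherwise with the Wilcoxon signed-rank
    test (exact null distribution where SciPy supports it).  All-equal
    differences are degenerate: p = 1 by convention, flagged.
    """
    nc = np.asarray(nc_values, dtype=float)
    cap = np.asarray(cap_values, dtype=float)
    if nc.shape != cap.shape or nc.ndim != 1:
        raise ValueError("nc and cap must be 1-D arrays of equal length")
    if len(nc) < 3:
        raise ValueError("paired comparison requires at least 3 pairs")
    diffs = cap - nc
    base = dict(
        n=len(nc),
        mean_nc=float(np.mean(nc)),
        sem_nc=_sem(nc),
        mean_cap=float(np.mean(cap)),
        sem_cap=_sem(cap),
        mean_diff=float(np.mean(diffs)),
        sem_diff=_sem(diffs),
    )
    if np.ptp(diffs) == 0:
        return PairedTestReport(
            test="degenerate",
            statistic=float("nan"),
            p_value=1.0,
            shapiro_p=float("nan"),
            degenerate=True,
            **base,
        )
    shapiro_p = float(stats.shapiro(diffs).pvalue)
    if shapiro_p >= SHAPIRO_ALPHA:
        res = stats.ttest_rel(cap, nc)
        return PairedTestReport(
            test="paired t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            shapiro_p=shapiro_p,
            **base,
        )
    res = stats.wilcoxon(cap, nc, method="auto")
    return PairedTestReport(
        test="wilcoxon signed-rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p=shapiro_p,
        **base,
    )


def delta_vs_zero(deltas) -> OneSampleReport:
    """One-sample t-test of per-sample deltas against a theoretical mean of 0."""
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValueError("need at least 3 deltas")
    if np.ptp(d) == 0 and d[0] == 0:
        return OneSampleReport(float("nan"), 1.0, len(d), 0.0, 0.0, degenerate=True)
    if np.ptp(d) == 0:
        # identical non-zero deltas: zero variance, t undefined
        return OneSampleReport(
            float("nan"), 1.0, len(d), float(d[0]), 0.0, degenerate=True
        )
    res = stats.ttest_1samp(d, 0.0)
    return OneSampleReport(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(d),
        mean=float(np.mean(d)),
        sem=_sem(d),
    )


def _percent_half_up(count: int, n: int) -> int:
    return int(math.floor(100.0 * count / n + 0.5))


@dataclass
class CohortSummary:
    """Per-category counts and integer percentages for one donor class."""

    donor_class: str
    n: int
    counts: dict[str, int] = field(default_factory=dict)
    percents: dict[str, int] = field(default_factory=dict)

    def rows(self, parameter: str = "") -> list[dict]:
        return [
            {
                "donor_class": self.donor_class,
                "parameter": parameter,
                "category": cat,
                "count": cnt,
                "percent": self.percents[cat],
            }
            for cat, cnt in self.counts.items()
        ]


def summarize_cohort(categories, donor_class: str) -> CohortSummary:
    """Count classification categories and report rounded percentages.

    Percentages use half-up rounding to integers; counts always sum to
    n exactly, percentages to 100 within rounding slack.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("cannot summarize an empty category list")
    counts: dict[str, int] = {}
    for c in cats:
        counts[c] = counts.get(c, 0) + 1
    n = len(cats)
    percents = {c: _percent_half_up(k, n) for c, k in counts.items()}
    return CohortSummary(donor_class=donor_class, n=n, counts=counts, percents=percents)
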