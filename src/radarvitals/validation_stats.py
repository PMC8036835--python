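"""Agreement statistics between radar-extracted and reference vital rates.

The battery is the standard method-comparison toolkit:

* ICC(2,1) — two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation, computed from the two-way ANOVA mean squares.
  Values of 0.7-1.0 are conventionally read as high reliability.
* Bland–Altman — mean difference (bias) and 95% limits of agreement
  (bias ± 1.96 × SD of the differences).
* Ordinary least squares of radar on reference, reported against the
  identity line (slope 1, intercept 0).
* Kruskal–Wallis H comparing the pooled rank distributions of the two
  series (two groups, chi-square approximation, tie-corrected).

Note the rank test compares distributions, not paired agreement: a small
p-value means the two methods' value distributions differ.  The report
returns H and p without further interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError
from .synthetic_data import ReferenceRecord
from .vitals_extraction import VitalsEstimate

__all__ = [
    "PairedRates",
    "AgreementReport",
    "align_rates",
    "icc",
    "bland_altman",
    "regression_identity",
    "kruskal_wallis",
    "agreement_report",
    "bland_altman_plot",
]


@dataclass
class PairedRates:
    """Time-aligned radar/reference rate pairs (bpm)."""

    radar: np.ndarray
    reference: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.radar = np.asarray(self.radar, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.radar.shape != self.reference.shape or self.radar.ndim != 1:
            raise UndefinedStatisticError("radar/reference must be equal-length 1-D")
        if len(self.radar) < 2:
            raise UndefinedStatisticError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.radar)) and np.all(np.isfinite(self.reference))):
            raise UndefinedStatisticError("rates must be finite")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n(self) -> int:
        return len(self.radar)


@dataclass
class AgreementReport:
    """All agreement statistics for one paired rate series."""

    icc: float
    bias: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r: float
    kw_h: float
    kw_p: float
    n: int

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame([asdict(self)]).to_csv(path, index=False, float_format="%.6f")
        return path

    def summary(self) -> str:
        return (
            f"n = {self.n} pairs\n"
            f"ICC(2,1)           : {self.icc:.3f}\n"
            f"Bland-Altman bias  : {self.bias:+.2f} bpm\n"
            f"Limits of agreement: [{self.loa_low:+.2f}, {self.loa_high:+.2f}] bpm\n"
            f"Regression         : radar = {self.slope:.3f} * reference "
            f"{self.intercept:+.2f}  (r = {self.r:.3f})\n"
            f"Kruskal-Wallis     : H = {self.kw_h:.3f}, p = {self.kw_p:.4g}\n"
        )


def align_rates(
    estimate: VitalsEstimate,
    reference: ReferenceRecord,
    which: str = "hr",
) -> PairedRates:
    """Pair each valid radar window with the nearest per-second reference readout.

    ``which`` selects ``"hr"`` or ``"br"``.  Windows flagged invalid (body
    movement) are dropped.  Reference readout ``i`` covers second ``i``; the
    nearest readout to a window centered at ``t`` is ``round(t - 0.5)``
    clipped into range (no interpolation).
    """
    if which not in ("hr", "br"):
        raise ValueError("which must be 'hr' or 'br'")
    radar = estimate.hr if which == "hr" else estimate.br
    series = reference.hr_series if which == "hr" else reference.br_series
    mask = estimate.valid & np.isfinite(radar)
    t = estimate.times[mask] - reference.start_time
    idx = np.clip(np.round(t - 0.5).astype(int), 0, len(series) - 1)
    return PairedRates(radar=radar[mask], reference=series[idx],
                       times=estimate.times[mask])


def icc(pairs: PairedRates) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    With n targets and k=2 raters and the two-way ANOVA mean squares (rows =
    targets MSR, columns = raters MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))
    """
    x = np.column_stack([pairs.radar, pairs.reference])  # n x k
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("ICC undefined: zero denominator")
    return float((msr - mse) / denom)


def bland_altman(pairs: PairedRates) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high): mean difference and bias ± 1.96 × SD(diff).

    Differences are radar − reference; the SD uses the n−1 denominator.
    """
    diffs = pairs.radar - pairs.reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def regression_identity(pairs: PairedRates) -> tuple[float, float, float]:
    """(slope, intercept, r) of OLS radar-on-reference; identity = (1, 0)."""
    if np.ptp(pairs.reference) == 0:
        raise UndefinedStatisticError("regression undefined: constant reference")
    res = stats.linregress(pairs.reference, pairs.radar)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def kruskal_wallis(pairs: PairedRates) -> tuple[float, float]:
    """Two-group Kruskal–Wallis H (tie-corrected) on radar vs reference values.

    p comes from the chi-square approximation with 1 degree of freedom.  A
    small p says the two value distributions differ in location.
    """
    if np.ptp(np.concatenate([pairs.radar, pairs.reference])) == 0:
        raise UndefinedStatisticError("Kruskal-Wallis undefined: all values tied")
    h, p = stats.kruskal(pairs.radar, pairs.reference)
    return float(h), float(p)


def agreement_report(pairs: PairedRates) -> AgreementReport:
    """Compute the full agreement battery for one paired series."""
    bias, lo, hi = bland_altman(pairs)
    slope, intercept, r = regression_identity(pairs)
    try:
        h, p = kruskal_wallis(pairs)
    except UndefinedStatisticError:
        h, p = 0.0, 1.0  # identical constant-free case: no distributional difference
    return AgreementReport(
        icc=icc(pairs), bias=bias, loa_low=lo, loa_high=hi,
        slope=slope, intercept=intercept, r=r, kw_h=h, kw_p=p, n=pairs.n,
    )


def bland_altman_plot(pairs: PairedRates, ax=None, label: str = "rate"):
    """Difference-vs-mean scatter with bias and limit-of-agreement lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    means = (pairs.radar + pairs.reference) / 2.0
    diffs = pairs.radar - pairs.reference
    bias, lo, hi = bland_altman(pairs)
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(bias, color="tab:red", label=f"bias {bias:+.2f}")
    for y in (lo, hi):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel(f"mean {label} (bpm)")
    ax.set_ylabel("radar - reference (bpm)")
    ax.legend()
    return ax
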