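"""Cross-focus statistics: size-vs-movement regressions, aggregate-count
summaries, distribution comparisons and prion-induction frequencies.

These are the result-level computations of the pipeline.  Group
comparisons delegate to standard routines (Welch's t, paired t,
two-sample Kolmogorov–Smirnov); p-values are reported unadjusted by
default, with an optional Holm correction helper for users running many
pairwise tests.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .trajectory_io import CountTable


@dataclass
class RegressionResult:
    """Ordinary least-squares line with a two-sided slope test."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValidationError("regression needs n >= 3")


@dataclass
class InductionCount:
    """Plate counts and derived [PSI+] induction frequency.

    Roughly 100 cells are plated on permissive medium (giving
    ``cfu_total`` colony-forming units) and a ``density_factor``-fold
    higher density on selective medium; the induction frequency is
    colonies_selective / (cfu_total × density_factor).
    """

    colonies_selective: int
    cfu_total: int
    density_factor: float = 100.0

    def __post_init__(self) -> None:
        if self.colonies_selective < 0:
            raise ValidationError("colonies_selective must be >= 0")
        if self.cfu_total <= 0:
            raise ValidationError("cfu_total must be positive")
        if self.density_factor <= 0:
            raise ValidationError("density_factor must be positive")

    @property
    def frequency(self) -> float:
        return self.colonies_selective / (self.cfu_total * self.density_factor)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass
class CountSummary:
    """Aggregates-per-cell summary for one group of cells."""

    group: str
    n_cells: int
    percent_single: float  # % of cells with exactly one aggregate
    percent_multiple: float
    mean_count: float
    distribution: dict[int, int]  # count value -> number of cells


def volume_movement_regression(x, y) -> RegressionResult:
    """OLS of a movement parameter (gamma or sigma) on focus volume or
    focus:cell volume ratio, with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValidationError("need >= 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if np.ptp(y) == 0:  # constant response: slope 0, nothing explained
        r2, p = 0.0, 1.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=int(x.size),
    )


def aggregate_count_summary(counts: CountTable) -> dict[str, CountSummary]:
    """Per-group aggregates-per-cell summaries (percent single, mean, full
    distribution)."""
    out: dict[str, CountSummary] = {}
    for group in counts.groups:
        vals = counts.group_counts(group)
        n = vals.size
        single = int(np.sum(vals == 1))
        out[group] = CountSummary(
            group=group,
            n_cells=n,
            percent_single=100.0 * single / n,
            percent_multiple=100.0 * (n - single) / n,
            mean_count=float(np.mean(vals)),
            distribution=dict(sorted(Counter(vals.tolist()).items())),
        )
    return out


def group_comparison(a, b, method: str = "welch_t") -> TestResult:
    """Two-sided comparison of two samples.

    ``welch_t`` (default, unequal variances), ``paired_t`` (equal-length
    paired samples) or ``ks`` (two-sample Kolmogorov–Smirnov, sensitive
    to spread changes as well as location).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    if method == "welch_t":
        r = stats.ttest_ind(a, b, equal_var=False)
    elif method == "paired_t":
        if a.size != b.size:
            raise ValidationError("paired_t requires equal-length samples")
        if np.ptp(a - b) == 0:
            raise ValidationError(
                "zero within-pair variance; paired t-test is degenerate"
            )
        r = stats.ttest_rel(a, b)
    elif method == "ks":
        r = stats.ks_2samp(a, b)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return TestResult(
        statistic=float(r.statistic), p_value=float(r.pvalue), method=method
    )


def induction_frequency(
    colonies_selective: int, cfu_total: int, density_factor: float = 100.0
) -> InductionCount:
    """Induction frequency from plate counts: colonies on selective medium
    over total CFUs plated there (cfu_total × density_factor)."""
    return InductionCount(
        colonies_selective=int(colonies_selective),
        cfu_total=int(cfu_total),
        density_factor=float(density_factor),
    )


def fold_change(a: InductionCount, b: InductionCount) -> float:
    """Ratio of induction frequencies a / b."""
    if b.frequency == 0:
        raise ValidationError("reference frequency is zero")
    return a.frequency / b.frequency


def mean_induction_frequency(
    counts: list[InductionCount], exclude_above: float | None = None
) -> float:
    """Mean frequency across transformant replicates.

    ``exclude_above`` optionally drops outlier replicates whose frequency
    exceeds the given value before averaging (the averaging convention is
    exposed rather than fixed; default keeps everything).
    """
    freqs = np.array([c.frequency for c in counts], dtype=float)
    if exclude_above is not None:
        freqs = freqs[freqs <= exclude_above]
    if freqs.size == 0:
        raise ValidationError("no replicates left to average")
    return float(np.mean(freqs))


def adjust_pvalues(p_values, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment for a family of pairwise tests (off the
    main path; unadjusted p-values are the default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method=method)[1]
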