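"""Ensemble statistics for force distributions.

A force ensemble (adhesion or friction) is summarised the way single-molecule
force spectroscopy studies report it: the most likely force is the centre of a
Gaussian fitted to the force histogram (robust to outlier events), spread is
shown as box statistics, condition-to-condition changes as integer percent
reductions, and group differences are tested with Welch's unpaired t-test and
annotated with significance stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError

#: star annotation thresholds; "methods" is the conventional table, "captions"
#: the stricter ** cut some figure legends use.
STAR_TABLES = {
    "methods": ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*")),
    "captions": ((0.0001, "****"), (0.001, "***"), (0.005, "**"), (0.05, "*")),
}


@dataclass(frozen=True)
class GaussianPeakFit:
    """Gaussian fitted to a force histogram: A*exp(-(x-mu)^2 / (2 sigma^2))."""

    peak: float
    sd: float
    amplitude: float
    peak_se: float
    converged: bool
    bin_width: float


@dataclass(frozen=True)
class BoxStats:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    n: int
    outlier_count: int


@dataclass(frozen=True)
class SignificanceResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str
    degenerate: bool = False


def freedman_diaconis_bin_width(values: np.ndarray) -> float:
    """Freedman-Diaconis histogram bin width 2*IQR/n^(1/3)."""
    q1, q3 = np.percentile(values, [25, 75])
    return 2.0 * (q3 - q1) / values.size ** (1.0 / 3.0)


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_peak(
    values: Sequence[float], bin_width: Optional[float] = None
) -> GaussianPeakFit:
    """Fit a Gaussian to the histogram of ``values`` and report its centre.

    Bins default to the Freedman-Diaconis width.  Initialisation: centre at
    the modal bin midpoint, width at the sample SD, amplitude at the maximum
    count; the width is bounded positive.  A fit that cannot converge (e.g.
    all-equal input) is reported with ``converged=False``, never raised.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 30:
        raise ParameterError(f"need at least 30 values for a histogram fit, got {x.size}")
    if bin_width is None:
        bin_width = freedman_diaconis_bin_width(x)
    nan = float("nan")
    if not np.isfinite(bin_width) or bin_width <= 0:
        return GaussianPeakFit(nan, nan, nan, nan, False, 0.0)

    # span a whole number of bins, padded symmetrically so extreme values sit
    # inside the outer bins rather than exactly on the outer edges
    span = float(np.ptp(x))
    n_bins = max(3, int(math.floor(span / bin_width)) + 1)
    start = float(x.min()) - (n_bins * bin_width - span) / 2.0
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 3:
        return GaussianPeakFit(nan, nan, nan, nan, False, float(bin_width))

    p0 = (counts.max(), centers[np.argmax(counts)], max(x.std(), bin_width / 2.0))
    try:
        popt, pcov = optimize.curve_fit(
            _gauss,
            centers,
            counts,
            p0=p0,
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return GaussianPeakFit(nan, nan, nan, nan, False, float(bin_width))
    peak_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else nan
    converged = bool(x.min() <= popt[1] <= x.max())
    return GaussianPeakFit(
        peak=float(popt[1]),
        sd=float(popt[2]),
        amplitude=float(popt[0]),
        peak_se=peak_se,
        converged=converged,
        bin_width=float(bin_width),
    )


def box_stats(values: Sequence[float]) -> BoxStats:
    """Box-plot statistics: linear-interpolation quartiles, 1.5*IQR whiskers."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("box_stats requires a non-empty input")
    if x.size < 5:
        raise ParameterError(f"box_stats requires n >= 5, got {x.size}")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n=int(x.size),
        outlier_count=int(x.size - inside.size),
    )


def percent_reduction(initial: float, final: float, rounded: bool = True):
    """Percent decrease from ``initial`` to ``final``.

    Returns 100*(initial-final)/initial, by default rounded to the nearest
    integer with ties going away from zero (so 37.5 -> 38 and -37.5 -> -38),
    matching how force reductions are conventionally quoted.
    """
    if not np.isfinite(initial) or initial <= 0:
        raise ParameterError(f"initial value must be finite and > 0, got {initial}")
    raw = 100.0 * (initial - final) / initial
    if not rounded:
        return raw
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw))


def stars_for_p(p_value: float, table: str = "methods") -> str:
    """Map a p-value to a star annotation ('ns' above the loosest cut)."""
    if not 0.0 <= p_value <= 1.0:
        raise ParameterError(f"p_value must be in [0, 1], got {p_value}")
    for cut, label in STAR_TABLES[table]:
        if p_value < cut:
            return label
    return "ns"


def welch_t_test(
    group_a: Sequence[float], group_b: Sequence[float], star_table: str = "methods"
) -> SignificanceResult:
    """Two-sided unpaired Welch t-test with star annotation.

    Uses the Welch statistic and Welch-Satterthwaite degrees of freedom.  The
    degenerate case of two zero-variance groups with equal means is reported
    as t=0, p=1 with the ``degenerate`` flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return SignificanceResult(0.0, float(a.size + b.size - 2), 1.0,
                                      stars_for_p(1.0, star_table), degenerate=True)
        return SignificanceResult(float("inf"), float(a.size + b.size - 2), 0.0,
                                  stars_for_p(0.0, star_table), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return SignificanceResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=p,
        stars=stars_for_p(p, star_table),
    )
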