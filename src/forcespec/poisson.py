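"""Poisson decomposition of adhesion forces into specific and non-specific parts.

If each tip-sample contact ruptures an integer number of discrete bonds of
fixed force F_i on top of a non-specific offset F_0, and the bond count is
Poisson distributed, then across ensembles of contacts the variance of the
adhesion force is linear in its mean:

    sigma^2 = mu * F_i - F_i * F_0

so a straight-line fit of group variance on group mean yields the per-bond
specific force F_i as the slope and the non-specific force F_0 as
-intercept/slope.  Measurement noise adds its variance to every group and is
deliberately not subtracted (a known, documented bias source).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdhesionGroup:
    """Mean/variance summary of one group of adhesion forces."""

    group_id: str
    mu_m: float          # group mean adhesion, pN
    sigma2_m: float      # unbiased group variance, pN^2
    n: int

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ParameterError(f"group {self.group_id}: n must be >= 5, got {self.n}")
        if self.sigma2_m < 0:
            raise ParameterError(
                f"group {self.group_id}: sigma2_m must be >= 0, got {self.sigma2_m}"
            )


@dataclass(frozen=True)
class PoissonDecomposition:
    """Fitted variance-mean line and the forces it implies.

    ``valid`` is False when the sign structure contradicts the model (slope
    <= 0 or intercept >= 0); the raw fit is still returned, never negated.
    """

    f_i: float
    f_0: float
    f_i_se: float
    f_0_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    n_groups: int
    valid: bool


def group_curves(
    adhesions: Sequence[float],
    group_size: int = 30,
    scheme: str = "sequential",
    seed: Optional[int] = None,
    positions: Optional[Sequence[float]] = None,
) -> list[AdhesionGroup]:
    """Partition adhesion forces into disjoint groups and summarise each.

    Schemes: ``sequential`` chunks in acquisition order, ``random`` shuffles
    first (seeded), ``spatial`` sorts by a caller-supplied 1-D acquisition
    coordinate before chunking.  Curves left over after the last full group
    are dropped and logged.
    """
    values = np.asarray(adhesions, dtype=float)
    if group_size < 5:
        raise ParameterError(f"group_size must be >= 5, got {group_size}")
    if values.size < 2 * group_size:
        raise ParameterError(
            f"need at least 2*group_size={2 * group_size} curves, got {values.size}"
        )
    if scheme == "sequential":
        order = np.arange(values.size)
    elif scheme == "random":
        order = np.random.default_rng(seed).permutation(values.size)
    elif scheme == "spatial":
        if positions is None:
            raise ParameterError("spatial grouping requires per-curve positions")
        positions = np.asarray(positions, dtype=float)
        if positions.shape != values.shape:
            raise ParameterError("positions must match adhesions in length")
        order = np.argsort(positions, kind="stable")
    else:
        raise ParameterError(f"unknown grouping scheme {scheme!r}")

    n_groups = values.size // group_size
    dropped = values.size - n_groups * group_size
    if dropped:
        logger.info("group_curves: dropping %d leftover curve(s)", dropped)
    groups = []
    for g in range(n_groups):
        chunk = values[order[g * group_size : (g + 1) * group_size]]
        groups.append(
            AdhesionGroup(
                group_id=f"g{g:03d}",
                mu_m=float(chunk.mean()),
                sigma2_m=float(chunk.var(ddof=1)),
                n=group_size,
            )
        )
    return groups


def fit_poisson_decomposition(
    groups: Sequence[AdhesionGroup], weighted: bool = False
) -> PoissonDecomposition:
    """OLS fit of group variance on group mean; slope F_i, -intercept/slope F_0.

    ``weighted=True`` weights groups by their curve counts (WLS).  The
    standard error of F_0 follows by first-order (delta-method) propagation
    from the slope/intercept covariance.
    """
    if len(groups) < 3:
        raise ParameterError(f"need at least 3 groups, got {len(groups)}")
    mu = np.array([g.mu_m for g in groups], dtype=float)
    s2 = np.array([g.sigma2_m for g in groups], dtype=float)
    if np.ptp(mu) == 0:
        raise ParameterError("all group means are equal; variance-mean fit is degenerate")

    X = sm.add_constant(mu)
    if weighted:
        model = sm.WLS(s2, X, weights=np.array([g.n for g in groups], dtype=float))
    else:
        model = sm.OLS(s2, X)
    # HC3 covariance: residuals are variance-of-variance estimates whose
    # spread grows with the mean, and group counts are small, so the
    # small-sample heteroscedasticity-robust form keeps the reported SEs
    # honest (plain OLS SEs under-cover the slope here)
    res = model.fit(cov_type="HC3")
    intercept, slope = res.params
    cov = res.cov_params()
    var_b, var_a = cov[0, 0], cov[1, 1]
    cov_ab = cov[0, 1]

    if slope != 0:
        f_0 = -intercept / slope
        # delta method on f_0(a, b) = -b/a with a=slope, b=intercept
        d_da, d_db = intercept / slope**2, -1.0 / slope
        f_0_var = d_da**2 * var_a + d_db**2 * var_b + 2 * d_da * d_db * cov_ab
        f_0_se = float(np.sqrt(max(f_0_var, 0.0)))
    else:
        f_0, f_0_se = float("nan"), float("nan")

    return PoissonDecomposition(
        f_i=float(slope),
        f_0=float(f_0),
        f_i_se=float(np.sqrt(var_a)),
        f_0_se=f_0_se,
        intercept=float(intercept),
        intercept_se=float(np.sqrt(var_b)),
        r_squared=float(res.rsquared),
        n_groups=len(groups),
        valid=bool(slope > 0 and intercept < 0),
    )
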