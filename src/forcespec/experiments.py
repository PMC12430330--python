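"""Seeded simulation experiments used for end-to-end verification.

The central one regenerates the variance-mean decomposition under known
ground truth: ensembles of rupture forces are drawn from the compound Poisson
model at several bond-count levels, grouped, and refitted, replicate by
replicate, so recovery accuracy and coverage of the reported standard errors
can be measured directly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .poisson import fit_poisson_decomposition, group_curves
from .synthetic import AdhesionModelParams, draw_rupture_forces


def poisson_recovery_experiment(
    f_i: float,
    f_0: float,
    lambdas: Sequence[float],
    n_per_group: int,
    noise_sd: float,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Repeatedly simulate grouped ensembles and refit the decomposition.

    Each replicate draws ``n_per_group`` rupture forces per bond-count level
    (one group per level), fits variance on mean, and records the recovered
    specific force (slope), non-specific force (-intercept/slope), their
    standard errors and the fit R^2.  Returns one row per replicate.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates * len(lambdas))
    rows = []
    k = 0
    for _ in range(n_replicates):
        chunks = []
        for lam in lambdas:
            draw = draw_rupture_forces(
                AdhesionModelParams(
                    f_i=f_i,
                    f_0=f_0,
                    lambda_mean=float(lam),
                    noise_sd=noise_sd,
                    n_curves=n_per_group,
                    seed=int(seeds[k] % (2**31)),
                )
            )
            chunks.append(draw.forces)
            k += 1
        groups = group_curves(np.concatenate(chunks), group_size=n_per_group)
        decomp = fit_poisson_decomposition(groups)
        rows.append(
            {
                "f_i_hat": decomp.f_i,
                "f_i_se": decomp.f_i_se,
                "f_0_hat": decomp.f_0,
                "f_0_se": decomp.f_0_se,
                "r_squared": decomp.r_squared,
                "valid": decomp.valid,
            }
        )
    return pd.DataFrame(rows)
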