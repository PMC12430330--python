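#!/usr/bin/env python
"""Percent-reduction summaries: published tables and the simulated sweep.

Computes integer percent reductions (0 -> 100 mV/mm) of the specific and
non-specific forces directly from the published per-drug force tables, and
the same reductions for every channel of the simulated sweep report produced
by 02_run_sweep.py.  Writes results/reductions_published.tsv and
results/reductions_simulated.tsv.
"""

from pathlib import Path

import pandas as pd

from forcespec import reference as ref
from forcespec import reference_reduction_table
from forcespec.ensemble import percent_reduction

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    published = []
    for name, table in (("F_i", ref.SPECIFIC_FORCE_PN), ("F_0", ref.NONSPECIFIC_FORCE_PN)):
        t = reference_reduction_table(table)
        t.insert(0, "quantity", name)
        published.append(t)
        drugs_only = t[~t["drug"].str.contains(r"\(")]
        print(f"{name} reductions 0 -> 100 mV/mm: "
              f"{drugs_only['reduction_pct'].min()}-{drugs_only['reduction_pct'].max()}% "
              f"({t.iloc[-2]['drug']} ... {t.iloc[-1]['drug']})")
    pd.concat(published, ignore_index=True).to_csv(
        RESULTS / "reductions_published.tsv", sep="\t", index=False
    )

    sweep_path = RESULTS / "sweep_conditions.tsv"
    if not sweep_path.exists():
        print(f"{sweep_path} not found -- run analysis/02_run_sweep.py first")
        return
    conditions = pd.read_csv(sweep_path, sep="\t")
    rows = []
    for metric in ("adhesion_peak_pN", "loop_friction_pN", "cl_friction_pN",
                   "avg_height_nm", "sa_nm", "sq_nm"):
        for drug, sub in conditions.groupby("drug"):
            sub = sub.set_index("field_mv_mm")
            rows.append(
                {
                    "quantity": metric,
                    "drug": drug,
                    "initial": sub.loc[0, metric],
                    "final": sub.loc[100, metric],
                    "reduction_pct": percent_reduction(sub.loc[0, metric], sub.loc[100, metric]),
                }
            )
    simulated = pd.DataFrame(rows)
    simulated.to_csv(RESULTS / "reductions_simulated.tsv", sep="\t", index=False)
    for metric, sub in simulated.groupby("quantity"):
        print(f"simulated {metric}: reductions {sub['reduction_pct'].min()}-"
              f"{sub['reduction_pct'].max()}% across drugs")


if __name__ == "__main__":
    main()
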