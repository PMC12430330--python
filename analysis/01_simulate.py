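#!/usr/bin/env python
"""Generate a demonstration condition's raw data files and verify round-trips.

Writes a small batch of synthetic force curves, friction loops and a height
map for one condition (imatinib, 20 mV/mm) in the pipeline's TSV dialects
under scratch/demo_condition/, then reads everything back and checks that
the analysis recovers the generator's ground truth.
"""

from pathlib import Path

import numpy as np

from forcespec import (
    AdhesionModelParams,
    Calibration,
    CurveSynthesisParams,
    TopographyModelParams,
    draw_rupture_forces,
    extract_adhesion,
    friction_force,
    loop_half_width,
    read_curve,
    read_height_map,
    read_loop,
    surface_stats,
    synthesize_force_curve,
    synthesize_friction_loop,
    synthesize_height_map,
    write_curve,
    write_height_map,
    write_loop,
)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "demo_condition"


def main() -> None:
    (OUT / "curves").mkdir(parents=True, exist_ok=True)
    (OUT / "loops").mkdir(exist_ok=True)
    (OUT / "maps").mkdir(exist_ok=True)
    cal = Calibration()
    cparams = CurveSynthesisParams(noise_sd_signal=0.001, baseline_drift_slope=0.002)

    # imatinib @ 20 mV/mm operating point: F_i = 33.4 pN, F_0 = 90 pN
    draw = draw_rupture_forces(
        AdhesionModelParams(f_i=33.4, f_0=90.0, lambda_mean=8.0, noise_sd=25.0,
                            n_curves=20, seed=100)
    )
    errors = []
    for i, rupture in enumerate(draw.forces):
        curve = synthesize_force_curve(float(rupture), cparams, seed=200 + i,
                                       metadata={"sample_id": f"c{i:03d}",
                                                 "drug": "imatinib", "field_mv_mm": "20"})
        path = OUT / "curves" / f"curve_{i:03d}.tsv"
        write_curve(curve, path)
        event = extract_adhesion(read_curve(path, cal))
        errors.append(event.adhesion_force_pn - rupture)
    print(f"wrote 20 force curves; file round-trip adhesion error "
          f"max |err| = {np.max(np.abs(errors)):.2f} pN (noise floor)")

    vf_true = 8.91e-4  # half-width giving ~202 pN at the default calibration
    for i in range(20):
        loop = synthesize_friction_loop(vf_true, offset=0.3, noise_sd=0.001,
                                        n_points=512, seed=300 + i, load_nN=1.0)
        write_loop(loop, OUT / "loops" / f"loop_{i:03d}.tsv")
    loops = [read_loop(p) for p in sorted((OUT / "loops").glob("*.tsv"))]
    forces = [friction_force(loop_half_width(lp), cal) for lp in loops]
    print(f"wrote 20 friction loops; mean recovered friction "
          f"{np.mean(forces):.1f} pN (target {friction_force(vf_true, cal):.1f} pN)")

    hm = synthesize_height_map(TopographyModelParams(seed=400))
    write_height_map(hm, OUT / "maps" / "map_000.tsv")
    stats = surface_stats(read_height_map(OUT / "maps" / "map_000.tsv"))
    print(f"wrote 1 height map (512x512); layer {hm.grid.mean():.1f} nm mean height, "
          f"Sa {stats.sa:.2f} nm, Sq {stats.sq:.2f} nm (Sq target 2.6 nm)")


if __name__ == "__main__":
    main()
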