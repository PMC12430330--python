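"""Friction-loop analysis.

A friction loop is a forward (trace) and backward (retrace) lateral-signal
scan over the same fast-scan line.  Half the trace-retrace difference, V_f,
isolates the friction contribution (a common offset cancels), and the lateral
calibration converts it to a force:

    F_f = (3/2) * K_f * (h / l) * (V_f / S)

with K_f the lateral spring coefficient (N/m), h the tip height, l the
cantilever length (same length units; only the ratio enters) and S the
lateral detector sensitivity in signal units per nm, so V_f/S is a length and
the product is a force (reported in pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import PN_PER_NN, Calibration
from .errors import FormatError, ParameterError


@dataclass
class FrictionLoop:
    """Trace/retrace lateral signal over shared fast-scan positions (nm)."""

    x_nm: np.ndarray
    v_trace: np.ndarray
    v_retrace: np.ndarray
    load_nN: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.v_trace = np.asarray(self.v_trace, dtype=float)
        self.v_retrace = np.asarray(self.v_retrace, dtype=float)
        if not (self.x_nm.shape == self.v_trace.shape == self.v_retrace.shape):
            raise FormatError("trace and retrace must share the same positions")
        if self.x_nm.size < 2:
            raise FormatError(f"friction loop needs >= 2 points, got {self.x_nm.size}")


@dataclass(frozen=True)
class FrictionResult:
    v_f: float            # half-width, signal units
    f_f: float            # friction force, pN
    n_points: int
    load_nN: Optional[float]


def half_width_profile(loop: FrictionLoop) -> np.ndarray:
    """Per-position half-widths (trace - retrace)/2, for diagnostics."""
    return (loop.v_trace - loop.v_retrace) / 2.0


def loop_half_width(loop: FrictionLoop, central_fraction: float = 0.8) -> float:
    """Friction-loop half-width V_f.

    Averages (trace - retrace)/2 over the central ``central_fraction`` of the
    scan line (turnaround points at the line ends are excluded) and takes the
    absolute value, so the scan orientation does not affect the result.
    """
    if not 0 < central_fraction <= 1:
        raise ParameterError(f"central_fraction must be in (0, 1], got {central_fraction}")
    hw = half_width_profile(loop)
    n = hw.size
    margin = int(np.floor(n * (1.0 - central_fraction) / 2.0))
    central = hw[margin : n - margin] if margin else hw
    return float(abs(central.mean()))


def friction_force(v_f: float, calibration: Calibration) -> float:
    """Convert a half-width V_f (signal units) to a friction force in pN."""
    if v_f < 0:
        raise ParameterError(f"v_f must be >= 0 after orientation convention, got {v_f}")
    displacement_nm = v_f / calibration.lateral_sensitivity
    geometry = calibration.tip_height_um / calibration.cantilever_length_um
    return 1.5 * calibration.k_f * geometry * displacement_nm * PN_PER_NN


def friction_ensemble(
    loops: Sequence[FrictionLoop],
    calibration: Calibration,
    mode: str = "loop",
    central_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-loop friction forces for an ensemble of loops.

    ``mode='loop'`` processes every loop as-is; ``mode='constant-load'``
    additionally requires every loop to carry a load tag (nN) and records it,
    so ensembles at different loads can be partitioned downstream.  Returns a
    DataFrame with columns v_f, f_f_pN, n_points, load_nN plus any loop
    metadata keys.
    """
    if mode not in ("loop", "constant-load"):
        raise ParameterError(f"mode must be 'loop' or 'constant-load', got {mode!r}")
    if not loops:
        raise ParameterError("friction_ensemble needs at least one loop")
    if mode == "constant-load":
        missing = sum(1 for lp in loops if lp.load_nN is None)
        if missing:
            raise ParameterError(
                f"constant-load mode: {missing} loop(s) have no load tag"
            )
    rows = []
    for lp in loops:
        v_f = loop_half_width(lp, central_fraction=central_fraction)
        row = {
            "v_f": v_f,
            "f_f_pN": friction_force(v_f, calibration),
            "n_points": lp.x_nm.size,
            "load_nN": lp.load_nN,
        }
        row.update(lp.metadata)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV dialect: '# key: value' header comments (load_nN among them), then
# columns x_nm, v_trace, v_retrace.
# ---------------------------------------------------------------------------

def write_loop(loop: FrictionLoop, path) -> None:
    path = Path(path)
    lines = []
    if loop.load_nN is not None:
        lines.append(f"# load_nN: {loop.load_nN}")
    for key, value in loop.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("x_nm\tv_trace\tv_retrace")
    for x, t, r in zip(loop.x_nm, loop.v_trace, loop.v_retrace):
        lines.append(f"{x:.6g}\t{t:.9g}\t{r:.9g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_loop(path) -> FrictionLoop:
    path = Path(path)
    metadata = {}
    rows = []
    header = None
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            metadata[key.strip()] = value.strip()
        elif header is None:
            header = line.split("\t")
        else:
            rows.append(line.split("\t"))
    if header != ["x_nm", "v_trace", "v_retrace"]:
        raise FormatError(
            f"{path.name}: loop file must have columns x_nm, v_trace, v_retrace"
        )
    data = np.asarray(rows, dtype=float)
    load = metadata.pop("load_nN", None)
    return FrictionLoop(
        x_nm=data[:, 0],
        v_trace=data[:, 1],
        v_retrace=data[:, 2],
        load_nN=float(load) if load is not None else None,
        metadata=metadata,
    )
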