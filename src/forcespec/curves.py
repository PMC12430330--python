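"""Force-distance curve processing.

Raw records are deflection-signal-vs-piezo-position traces (one approach and
one retract segment per contact).  Hooke's law F = k*d converts the deflection
``d = sensitivity * signal`` into a force, and the adhesion force of a curve is
the magnitude of the maximum attractive (most negative) force on the retract
segment after baseline correction -- the force needed to separate tip and
sample.  Attractive forces are negative internally; reported adhesion is the
positive magnitude.

Units are fixed across the public contract: piezo position in nm, forces in
pN, spring constants in N/m.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: minimum points per curve segment
MIN_SEGMENT_POINTS = 16

#: 1 N/m * 1 nm = 1 nN = 1000 pN
PN_PER_NN = 1000.0

#: consistency factor turning a median absolute deviation into a Gaussian SD
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class Calibration:
    """Cantilever / detector calibration constants.

    Parameters
    ----------
    k : float
        Normal spring constant in N/m.
    sensitivity : float
        Normal deflection sensitivity, nm per signal unit.
    k_f : float
        Lateral (torsional) spring coefficient in N/m.
    tip_height_um, cantilever_length_um : float
        Tip height h and cantilever length l in micrometres; only their
        ratio enters the lateral force conversion.
    lateral_sensitivity : float
        Lateral-channel detector sensitivity S in signal units per nm.
    """

    k: float = 0.2
    sensitivity: float = 25.0
    k_f: float = 80.0
    tip_height_um: float = 17.0
    cantilever_length_um: float = 450.0
    lateral_sensitivity: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "k",
            "sensitivity",
            "k_f",
            "tip_height_um",
            "cantilever_length_um",
            "lateral_sensitivity",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(
                    f"Calibration.{name} must be finite and > 0, got {value!r}"
                )


def signal_to_force(signal, calibration: Calibration):
    """Convert a deflection signal to force in pN via F = k * d.

    The deflection is ``d = sensitivity * signal`` (nm); with k in N/m the
    product k*d is in nN and is scaled to pN.  Accepts scalars or arrays and
    is linear in the signal.
    """
    arr = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("signal contains non-finite values")
    force = calibration.k * calibration.sensitivity * arr * PN_PER_NN
    return force if arr.ndim else float(force)


def _check_segment(name: str, z: np.ndarray, sig: np.ndarray) -> None:
    if z.ndim != 1 or sig.ndim != 1 or z.shape != sig.shape:
        raise FormatError(f"{name} segment arrays must be 1-D and equal length")
    if z.size < MIN_SEGMENT_POINTS:
        raise FormatError(
            f"{name} segment has {z.size} points; at least {MIN_SEGMENT_POINTS} required"
        )
    dz = np.diff(z)
    if not (np.all(dz > 0) or np.all(dz < 0)):
        raise FormatError(f"{name} segment positions are not strictly monotone")


@dataclass
class ForceCurve:
    """One approach/retract cycle of piezo position (nm) vs deflection signal."""

    z_approach: np.ndarray
    signal_approach: np.ndarray
    z_retract: np.ndarray
    signal_retract: np.ndarray
    calibration: Calibration
    metadata: dict = field(default_factory=dict)
    #: (slope, intercept) of the baseline already subtracted, in signal units;
    #: None for an uncorrected curve
    baseline: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.z_approach = np.asarray(self.z_approach, dtype=float)
        self.signal_approach = np.asarray(self.signal_approach, dtype=float)
        self.z_retract = np.asarray(self.z_retract, dtype=float)
        self.signal_retract = np.asarray(self.signal_retract, dtype=float)
        _check_segment("approach", self.z_approach, self.signal_approach)
        _check_segment("retract", self.z_retract, self.signal_retract)

    def retract_force(self) -> np.ndarray:
        """Retract-segment forces in pN."""
        return signal_to_force(self.signal_retract, self.calibration)


@dataclass(frozen=True)
class AdhesionEvent:
    """Result of adhesion extraction from one retract segment.

    ``adhesion_force_pn`` is None when no unbinding event was detected --
    absence is never encoded as a zero force.  ``min_force_magnitude_pn``
    keeps the raw extremum for diagnostics regardless of the event flag.
    """

    adhesion_force_pn: Optional[float]
    rupture_position_nm: Optional[float]
    baseline_slope: float
    baseline_intercept: float
    has_event: bool
    threshold_pn: float
    min_force_magnitude_pn: float


def _tail_indices(z: np.ndarray, tail_fraction: float) -> np.ndarray:
    """Indices of the farthest ``tail_fraction`` of positions (largest z)."""
    n_tail = int(round(tail_fraction * z.size))
    order = np.argsort(z)
    return order[z.size - n_tail :]


def correct_baseline(curve: ForceCurve, tail_fraction: float = 0.3) -> ForceCurve:
    """Fit a line to the non-contact tail of the retract segment and subtract it.

    The tail is the farthest ``tail_fraction`` of retract positions, where the
    tip is out of contact and the signal should be flat; a least-squares line
    through it captures baseline offset and linear drift, and is subtracted
    from both segments so the non-contact force is zero-mean.
    """
    if not 0 < tail_fraction <= 1:
        raise ParameterError(f"tail_fraction must be in (0, 1], got {tail_fraction}")
    idx = _tail_indices(curve.z_retract, tail_fraction)
    if idx.size < 8:
        raise ParameterError(
            f"baseline tail has {idx.size} points; at least 8 required "
            f"(tail_fraction={tail_fraction})"
        )
    z_tail = curve.z_retract[idx]
    sig_tail = curve.signal_retract[idx]
    if np.ptp(z_tail) == 0:
        slope, intercept = 0.0, float(np.mean(sig_tail))
    else:
        slope, intercept = np.polyfit(z_tail, sig_tail, 1)
    corrected = replace(
        curve,
        signal_approach=curve.signal_approach - (slope * curve.z_approach + intercept),
        signal_retract=curve.signal_retract - (slope * curve.z_retract + intercept),
        baseline=(float(slope), float(intercept)),
    )
    return corrected


def extract_adhesion(
    curve: ForceCurve,
    threshold_sigma: float = 5.0,
    tail_fraction: float = 0.3,
) -> AdhesionEvent:
    """Extract the adhesion force from a (baseline-corrected) retract segment.

    The adhesion force is the magnitude of the most attractive corrected force
    on retraction.  An unbinding event is declared when that magnitude reaches
    ``threshold_sigma`` times a robust (MAD-based) estimate of the baseline
    noise SD; a magnitude exactly at the threshold counts as an event.  Curves
    that never dip below the baseline report no event.
    """
    if curve.baseline is None:
        curve = correct_baseline(curve, tail_fraction=tail_fraction)
    slope, intercept = curve.baseline

    force = curve.retract_force()
    tail = force[_tail_indices(curve.z_retract, tail_fraction)]
    noise_sd = MAD_TO_SD * float(np.median(np.abs(tail - np.median(tail))))
    threshold = threshold_sigma * noise_sd

    i_min = int(np.argmin(force))
    magnitude = max(0.0, -float(force[i_min]))
    has_event = magnitude > 0 and magnitude >= threshold
    return AdhesionEvent(
        adhesion_force_pn=magnitude if has_event else None,
        rupture_position_nm=float(curve.z_retract[i_min]) if has_event else None,
        baseline_slope=slope,
        baseline_intercept=intercept,
        has_event=has_event,
        threshold_pn=threshold,
        min_force_magnitude_pn=magnitude,
    )


# ---------------------------------------------------------------------------
# TSV dialect: UTF-8, '# key: value' metadata header, then a header line with
# columns 'segment' (approach|retract), 'z_nm', 'signal'; one file per curve.
# ---------------------------------------------------------------------------

def write_curve(curve: ForceCurve, path) -> None:
    """Write a curve in the TSV dialect (metadata as '# key: value' lines)."""
    path = Path(path)
    buf = io.StringIO()
    for key, value in curve.metadata.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("segment\tz_nm\tsignal\n")
    for seg, z, sig in (
        ("approach", curve.z_approach, curve.signal_approach),
        ("retract", curve.z_retract, curve.signal_retract),
    ):
        for zi, si in zip(z, sig):
            buf.write(f"{seg}\t{zi:.6g}\t{si:.9g}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_curve(path, calibration: Calibration) -> ForceCurve:
    """Read a curve written by :func:`write_curve`."""
    path = Path(path)
    metadata = {}
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            metadata[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    table = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
    required = {"segment", "z_nm", "signal"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"{path.name}: curve file must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    segs = {}
    for name in ("approach", "retract"):
        part = table[table["segment"] == name]
        if part.empty:
            raise FormatError(f"{path.name}: missing '{name}' segment")
        segs[name] = (part["z_nm"].to_numpy(float), part["signal"].to_numpy(float))
    return ForceCurve(
        z_approach=segs["approach"][0],
        signal_approach=segs["approach"][1],
        z_retract=segs["retract"][0],
        signal_retract=segs["retract"][1],
        calibration=calibration,
        metadata=metadata,
    )
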