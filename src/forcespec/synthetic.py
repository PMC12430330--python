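"""Synthetic force-spectroscopy data with known ground truth.

Every downstream stage of the pipeline is exercised against data generated
here, so each generator realises exactly the statistical structure the
corresponding analysis assumes:

* rupture forces: ``f = f_0 + N * f_i + eps`` with a Poisson bond count
  ``N ~ Poisson(lambda_mean)`` and Gaussian measurement noise ``eps``; the
  ensemble mean is ``f_0 + lambda * f_i`` and the variance
  ``lambda * f_i^2 + noise_sd^2``, which is what the variance-mean
  decomposition inverts;
* force curves: a piecewise-linear approach/retract pair with a contact ramp,
  a flat non-contact baseline (optionally drifting), and a single adhesion
  well on retraction whose depth equals the requested rupture force with the
  jump-off placed exactly on the sampling grid;
* friction loops: ``trace = offset + v_f + noise``,
  ``retrace = offset - v_f + noise``, so the loop half-width recovers v_f;
* height maps: a flat substrate plus randomly placed Gaussian protein bumps,
  with a multiplicative compaction factor standing in phenomenologically for
  field-induced flattening.

All randomness flows from an explicit per-call seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curves import PN_PER_NN, Calibration, ForceCurve
from .errors import ParameterError
from .friction import FrictionLoop
from .topography import HeightMap


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ParameterError(message)


@dataclass(frozen=True)
class AdhesionModelParams:
    """Ground truth for a rupture-force ensemble.

    f_i : per-bond specific force, pN (> 0)
    f_0 : non-specific offset, pN (>= 0)
    lambda_mean : mean bond count per contact (> 0; 0 allowed for the
        degenerate no-bond case)
    noise_sd : Gaussian measurement noise on the rupture force, pN (>= 0)
    """

    f_i: float
    f_0: float
    lambda_mean: float
    noise_sd: float
    n_curves: int
    seed: int

    def __post_init__(self) -> None:
        _require(self.f_i > 0, f"f_i must be > 0, got {self.f_i}")
        _require(self.f_0 >= 0, f"f_0 must be >= 0, got {self.f_0}")
        _require(self.lambda_mean >= 0, f"lambda_mean must be >= 0, got {self.lambda_mean}")
        _require(self.noise_sd >= 0, f"noise_sd must be >= 0, got {self.noise_sd}")
        _require(self.n_curves >= 1, f"n_curves must be >= 1, got {self.n_curves}")


@dataclass(frozen=True)
class RuptureDraw:
    """Drawn rupture forces plus a flag for draws clipped at zero."""

    forces: np.ndarray
    clipped: np.ndarray  # boolean mask, True where a negative draw was clipped

    @property
    def n_clipped(self) -> int:
        return int(self.clipped.sum())


def draw_rupture_forces(params: AdhesionModelParams) -> RuptureDraw:
    """Draw an ensemble of rupture forces from the compound Poisson model.

    Negative draws (possible at high noise) are clipped to zero and flagged
    rather than silently kept: physical forces are non-negative and the flag
    preserves auditability.
    """
    rng = np.random.default_rng(params.seed)
    bonds = rng.poisson(params.lambda_mean, params.n_curves)
    noise = (
        rng.normal(0.0, params.noise_sd, params.n_curves)
        if params.noise_sd > 0
        else np.zeros(params.n_curves)
    )
    raw = params.f_0 + bonds * params.f_i + noise
    clipped = raw < 0
    return RuptureDraw(forces=np.where(clipped, 0.0, raw), clipped=clipped)


@dataclass(frozen=True)
class CurveSynthesisParams:
    """Geometry and noise of synthetic force-distance curves.

    spring_constant : cantilever normal stiffness, N/m
    sensitivity : deflection sensitivity, nm per signal unit
    sample_spacing : piezo step, nm (the discretization of every feature)
    contact_stiffness_fraction : slope of the contact ramp relative to the
        cantilever stiffness, in (0, 1]
    baseline_drift_slope : linear baseline drift, signal units per nm
    noise_sd_signal : additive Gaussian noise, signal units
    contact_depth_nm / z_max_nm : extent of the piezo sweep below and above
        the contact point
    """

    spring_constant: float = 0.2
    sensitivity: float = 25.0
    sample_spacing: float = 0.25
    contact_stiffness_fraction: float = 1.0
    baseline_drift_slope: float = 0.0
    noise_sd_signal: float = 0.0
    contact_depth_nm: float = 5.0
    z_max_nm: float = 100.0

    def __post_init__(self) -> None:
        _require(self.spring_constant > 0, f"spring_constant must be > 0, got {self.spring_constant}")
        _require(self.sensitivity > 0, f"sensitivity must be > 0, got {self.sensitivity}")
        _require(self.sample_spacing > 0, f"sample_spacing must be > 0, got {self.sample_spacing}")
        _require(
            0 < self.contact_stiffness_fraction <= 1,
            f"contact_stiffness_fraction must be in (0, 1], got {self.contact_stiffness_fraction}",
        )
        _require(self.noise_sd_signal >= 0, f"noise_sd_signal must be >= 0, got {self.noise_sd_signal}")
        _require(self.z_max_nm > 0, f"z_max_nm must be > 0, got {self.z_max_nm}")

    def calibration(self) -> Calibration:
        return Calibration(k=self.spring_constant, sensitivity=self.sensitivity)


def synthesize_force_curve(
    rupture_force: float,
    params: CurveSynthesisParams,
    seed: Optional[int] = None,
    metadata: Optional[dict] = None,
) -> ForceCurve:
    """Build a piecewise-linear approach/retract curve with a known rupture.

    The piezo grid contains the contact point (z = 0) and the jump-off
    position exactly, so at zero noise the retract minimum equals the
    requested rupture force and round-trips through adhesion extraction to
    within floating-point error (well inside one sampling step).
    """
    _require(rupture_force >= 0, f"rupture_force must be >= 0, got {rupture_force}")
    ds = params.sample_spacing
    n_neg = int(np.ceil(params.contact_depth_nm / ds))
    n_pos = int(round(params.z_max_nm / ds))
    z = np.arange(-n_neg, n_pos + 1, dtype=float) * ds

    signal = np.zeros_like(z)
    in_contact = z < 0
    # contact ramp: deflection grows as the tip presses in
    signal[in_contact] = (
        params.contact_stiffness_fraction * (-z[in_contact]) / params.sensitivity
    )
    signal_approach = signal.copy()

    if rupture_force > 0:
        # jump-off deflection from Hooke's law, snapped onto the grid
        d_rup_nm = rupture_force / (params.spring_constant * PN_PER_NN)
        steps = int(np.clip(round(d_rup_nm / ds), 3, max(3, int(0.4 * n_pos))))
        z_rup = steps * ds
        well = (z >= 0) & (z <= z_rup)
        signal_rup = d_rup_nm / params.sensitivity
        signal[well] -= signal_rup * z[well] / z_rup

    rng = np.random.default_rng(seed)
    curves = {}
    for name, base in (("approach", signal_approach), ("retract", signal)):
        sig = base + params.baseline_drift_slope * z
        if params.noise_sd_signal > 0:
            sig = sig + rng.normal(0.0, params.noise_sd_signal, z.size)
        curves[name] = sig

    return ForceCurve(
        z_approach=z[::-1].copy(),
        signal_approach=curves["approach"][::-1].copy(),
        z_retract=z,
        signal_retract=curves["retract"],
        calibration=params.calibration(),
        metadata=metadata or {},
    )


def synthesize_friction_loop(
    true_vf: float,
    offset: float,
    noise_sd: float,
    n_points: int,
    seed: Optional[int] = None,
    x_extent_nm: float = 1000.0,
    load_nN: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> FrictionLoop:
    """Friction loop with a symmetric trace/retrace split of 2*true_vf.

    trace = offset + true_vf + noise and retrace = offset - true_vf + noise,
    so the loop half-width estimates true_vf and any common offset cancels.
    """
    _require(n_points >= 2, f"n_points must be >= 2, got {n_points}")
    _require(noise_sd >= 0, f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_extent_nm, n_points)
    noise_t = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    noise_r = rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else np.zeros(n_points)
    return FrictionLoop(
        x_nm=x,
        v_trace=offset + true_vf + noise_t,
        v_retrace=offset - true_vf + noise_r,
        load_nN=load_nN,
        metadata=metadata or {},
    )


@dataclass(frozen=True)
class TopographyModelParams:
    """Protein-layer topograph model: substrate plus Gaussian bumps.

    The default grid matches a 1 um x 1 um scan at 512 x 512 pixels over a
    substrate reference of 6.9 nm; bump density and amplitude are tuned so
    the default layer sits ~8.5 nm above the substrate with Sq ~2.6 nm.
    ``compaction_factor`` scales the bump field multiplicatively, emulating
    field-induced compaction (heights and roughness scale together).
    """

    grid_size: int = 512
    pixel_nm: float = 1000.0 / 512.0
    baseline_height: float = 6.9
    bump_count: int = 2100
    bump_height_mean: float = 1.6
    bump_height_sd: float = 0.5
    bump_sigma_nm: float = 20.0
    compaction_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.grid_size >= 16, f"grid_size must be >= 16, got {self.grid_size}")
        _require(self.pixel_nm > 0, f"pixel_nm must be > 0, got {self.pixel_nm}")
        _require(self.bump_count >= 0, f"bump_count must be >= 0, got {self.bump_count}")
        _require(self.bump_height_mean > 0, f"bump_height_mean must be > 0, got {self.bump_height_mean}")
        _require(self.bump_height_sd >= 0, f"bump_height_sd must be >= 0, got {self.bump_height_sd}")
        _require(self.bump_sigma_nm > 0, f"bump_sigma_nm must be > 0, got {self.bump_sigma_nm}")
        _require(
            0 < self.compaction_factor <= 1,
            f"compaction_factor must be in (0, 1], got {self.compaction_factor}",
        )


def synthesize_height_map(
    params: TopographyModelParams, metadata: Optional[dict] = None
) -> HeightMap:
    """Render the bump field onto the grid, deterministically under the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.grid_size
    bumps = np.zeros((n, n))
    sigma_px = params.bump_sigma_nm / params.pixel_nm
    half = int(np.ceil(4.0 * sigma_px))
    offsets = np.arange(-half, half + 1, dtype=float)

    centers = rng.uniform(0.0, n, size=(params.bump_count, 2))
    heights = np.clip(
        rng.normal(params.bump_height_mean, params.bump_height_sd, params.bump_count),
        0.0,
        None,
    )
    for (cy, cx), h in zip(centers, heights):
        iy, ix = int(round(cy)), int(round(cx))
        gy = np.exp(-((iy + offsets - cy) ** 2) / (2.0 * sigma_px**2))
        gx = np.exp(-((ix + offsets - cx) ** 2) / (2.0 * sigma_px**2))
        y0, y1 = max(0, iy - half), min(n, iy + half + 1)
        x0, x1 = max(0, ix - half), min(n, ix + half + 1)
        patch = np.outer(gy[y0 - (iy - half) : y1 - (iy - half)],
                         gx[x0 - (ix - half) : x1 - (ix - half)])
        bumps[y0:y1, x0:x1] += h * patch

    grid = params.baseline_height + params.compaction_factor * bumps
    return HeightMap(grid=grid, pixel_nm=params.pixel_nm, metadata=metadata or {})
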