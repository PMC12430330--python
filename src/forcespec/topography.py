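"""Surface topography metrics from height-map grids.

Tapping-mode topographs are stored as rectangular height grids (nm).  After
optional first-order plane leveling, three scalar descriptors summarise a
scan: the average surface height (mean height over the scanned area relative
to the reference plane -- a layer property, not a single-molecule size), the
average roughness Sa (mean absolute deviation from the mean plane) and the
RMS roughness Sq.  Sq >= Sa always (Cauchy-Schwarz), with equality when the
deviations have constant magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, ParameterError

MIN_GRID_SIDE = 16


@dataclass
class HeightMap:
    """Rectangular grid of heights (nm) with a lateral pixel scale."""

    grid: np.ndarray
    pixel_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or min(self.grid.shape) < MIN_GRID_SIDE:
            raise FormatError(
                f"height map must be a 2-D grid of at least "
                f"{MIN_GRID_SIDE}x{MIN_GRID_SIDE}, got shape {self.grid.shape}"
            )
        if self.pixel_nm <= 0:
            raise ParameterError(f"pixel_nm must be > 0, got {self.pixel_nm}")
        bad = int(np.count_nonzero(~np.isfinite(self.grid)))
        if bad:
            raise FormatError(f"height map contains {bad} non-finite cell(s)")


@dataclass(frozen=True)
class SurfaceStats:
    avg_height: float   # nm, relative to the reference plane
    sa: float           # nm, mean absolute deviation
    sq: float           # nm, RMS deviation
    leveling_order: int


def level_plane(height_map: HeightMap, order: int = 1) -> HeightMap:
    """Subtract a least-squares reference plane (order 1) or nothing (order 0)."""
    if order == 0:
        return replace(height_map, grid=height_map.grid.copy())
    if order != 1:
        raise ParameterError(f"leveling order must be 0 or 1, got {order}")
    ny, nx = height_map.grid.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    design = np.column_stack(
        [np.ones(ny * nx), xx.ravel().astype(float), yy.ravel().astype(float)]
    )
    coef, *_ = np.linalg.lstsq(design, height_map.grid.ravel(), rcond=None)
    plane = (design @ coef).reshape(ny, nx)
    return replace(height_map, grid=height_map.grid - plane)


def surface_stats(
    height_map: HeightMap,
    leveling_order: int = 1,
    reference_height: float = 0.0,
) -> SurfaceStats:
    """Average height and Sa/Sq roughness of a scan.

    The average height is computed on the grid as given, relative to
    ``reference_height`` (e.g. a bare-substrate level); roughness is computed
    on deviations from the mean of the plane-leveled grid (``leveling_order``
    1 by default, 0 to skip leveling), over the full scan area.
    """
    avg = float(height_map.grid.mean() - reference_height)
    leveled = level_plane(height_map, order=leveling_order).grid
    dev = leveled - leveled.mean()
    return SurfaceStats(
        avg_height=avg,
        sa=float(np.abs(dev).mean()),
        sq=float(np.sqrt((dev**2).mean())),
        leveling_order=leveling_order,
    )


# ---------------------------------------------------------------------------
# TSV dialect: a 3-line header (# rows: R / # cols: C / # pixel_nm: P)
# followed by the R x C matrix, tab-separated, one grid row per line.
# ---------------------------------------------------------------------------

def write_height_map(height_map: HeightMap, path) -> None:
    path = Path(path)
    ny, nx = height_map.grid.shape
    header = f"# rows: {ny}\n# cols: {nx}\n# pixel_nm: {height_map.pixel_nm}"
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, height_map.grid, fmt="%.6g", delimiter="\t")


def read_height_map(path, metadata: Optional[dict] = None) -> HeightMap:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        head = {}
        for _ in range(3):
            line = fh.readline()
            if not line.startswith("#"):
                raise FormatError(f"{path.name}: expected a 3-line '#' header")
            key, _, value = line.lstrip("# ").partition(":")
            head[key.strip()] = value.strip()
        grid = np.loadtxt(fh, delimiter="\t")
    for key in ("rows", "cols", "pixel_nm"):
        if key not in head:
            raise FormatError(f"{path.name}: header missing '{key}'")
    if grid.shape != (int(head["rows"]), int(head["cols"])):
        raise FormatError(
            f"{path.name}: grid shape {grid.shape} does not match header "
            f"({head['rows']} x {head['cols']})"
        )
    return HeightMap(grid=grid, pixel_nm=float(head["pixel_nm"]), metadata=metadata or {})
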