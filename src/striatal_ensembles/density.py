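"""2D kernel-density hotspot demarcation.

The striatal subdomains with maximal density of high-expressing cells are
demarcated per section: a product-Gaussian (axis-aligned bivariate
normal) kernel density estimate is evaluated on a square grid, and the
minimal superlevel set containing at least a target fraction (default
20%) of the cells is extracted as iso-contour polygons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE = 0.20
DEFAULT_GRID_N = 100


@dataclass
class DensityGrid:
    """Product-Gaussian KDE evaluated on an n x n grid."""

    density: np.ndarray  # (n, n), indexed [iy, ix]
    xs: np.ndarray  # grid x coordinates (n,)
    ys: np.ndarray  # grid y coordinates (n,)
    bandwidth: tuple[float, float]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear density at arbitrary (x, y) points (0 outside grid)."""
        interp = RegularGridInterpolator(
            (self.ys, self.xs), self.density, bounds_error=False, fill_value=0.0
        )
        pts = np.asarray(points, dtype=float)
        return interp(np.column_stack([pts[:, 1], pts[:, 0]]))


@dataclass
class DensityContour:
    """Superlevel-set demarcation of one section for one gene."""

    level: float
    polygons: MultiPolygon
    enclosed_fraction: float
    mean_puncta: float = float("nan")
    gene: str = ""
    condition: str = ""
    section_id: str = ""
    n_cells: int = 0

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygons.centroid
        return (c.x, c.y)


def nrd_bandwidth(values: np.ndarray) -> float:
    """Normal-reference bandwidth: 1.06 min(sd, IQR/1.34) m^(-1/5)."""
    values = np.asarray(values, dtype=float)
    m = values.size
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        spread = sd  # degenerate IQR; fall back to sd alone
    return 1.06 * spread * m ** (-0.2)


def kde2d(
    points,
    bandwidth: tuple[float, float] | None = None,
    grid_n: int = DEFAULT_GRID_N,
) -> DensityGrid:
    """Axis-aligned bivariate normal KDE on a square grid.

    The grid spans the data bounding box padded by three bandwidths per
    axis. Bandwidths default to the per-axis normal reference rule.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) points")
    if bandwidth is None:
        hx, hy = nrd_bandwidth(pts[:, 0]), nrd_bandwidth(pts[:, 1])
        if hx <= 0 or hy <= 0:
            raise ValueError(
                "degenerate point set (all points identical on an axis); "
                "supply an explicit bandwidth"
            )
    else:
        hx, hy = bandwidth
        if hx <= 0 or hy <= 0:
            raise ValueError("bandwidths must be positive")

    xs = np.linspace(pts[:, 0].min() - 3 * hx, pts[:, 0].max() + 3 * hx, grid_n)
    ys = np.linspace(pts[:, 1].min() - 3 * hy, pts[:, 1].max() + 3 * hy, grid_n)
    # separable kernel: density[iy, ix] = mean_j phi_hx(xs[ix]-xj) phi_hy(ys[iy]-yj)
    dx = (xs[:, None] - pts[None, :, 0]) / hx
    dy = (ys[:, None] - pts[None, :, 1]) / hy
    kx = np.exp(-0.5 * dx**2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * dy**2) / (hy * np.sqrt(2 * np.pi))
    density = ky @ kx.T / pts.shape[0]
    return DensityGrid(density=density, xs=xs, ys=ys, bandwidth=(hx, hy))


def _rings_at_level(grid: DensityGrid, level: float) -> MultiPolygon:
    """Closed iso-contour polygons of the superlevel set at ``level``.

    The grid is padded with a sub-level border so that contours touching
    the grid edge close; rings nested inside another ring become holes
    (marching squares on the padded grid).
    """
    padded = np.full((grid.density.shape[0] + 2, grid.density.shape[1] + 2), -1.0)
    padded[1:-1, 1:-1] = grid.density
    dx = grid.xs[1] - grid.xs[0]
    dy = grid.ys[1] - grid.ys[0]
    rings = []
    for contour in measure.find_contours(padded, level):
        xs = grid.xs[0] + (contour[:, 1] - 1) * dx
        ys = grid.ys[0] + (contour[:, 0] - 1) * dy
        if len(xs) >= 4:
            ring = Polygon(np.column_stack([xs, ys]))
            if ring.is_valid and ring.area > 0:
                rings.append(ring)
    if not rings:
        return MultiPolygon([])
    rings.sort(key=lambda r: r.area, reverse=True)
    shells: list[Polygon] = []
    holes: dict[int, list] = {}
    for ring in rings:
        parent = next(
            (i for i, s in enumerate(shells) if s.contains(ring.representative_point())),
            None,
        )
        if parent is None:
            shells.append(ring)
            holes[len(shells) - 1] = []
        else:
            holes[parent].append(ring.exterior.coords)
    polys = [
        Polygon(s.exterior.coords, holes[i]).buffer(0) for i, s in enumerate(shells)
    ]
    flat: list[Polygon] = []
    for p in polys:
        flat.extend(p.geoms if isinstance(p, MultiPolygon) else [p])
    return MultiPolygon([p for p in flat if not p.is_empty])


def top_density_region(
    grid: DensityGrid,
    points,
    coverage: float = DEFAULT_COVERAGE,
) -> DensityContour:
    """Minimal superlevel set containing at least ``coverage`` of the cells.

    The level is the largest density lambda such that the fraction of
    points whose (bilinearly interpolated) density is >= lambda reaches
    the coverage target: the coverage-quantile from above of the
    per-point densities.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    pts = np.asarray(points, dtype=float)
    dens = grid.interpolate(pts)
    order = np.sort(dens)[::-1]
    n = len(order)
    m = int(np.ceil(coverage * n))
    level = float(order[m - 1])
    # Draw the rings a hair below lambda* so points *at* the level fall
    # inside (midway to the next lower point density; handles the
    # degenerate all-points-coincident case too). Marching-squares chords
    # can clip a boundary point of the bilinear superlevel set, so step
    # the drawn level down point-by-point until the literal cell-coverage
    # rule is met; the reported level stays lambda*.
    polys = MultiPolygon([])
    enclosed = 0.0
    k = m
    while k <= n:
        if k < n and order[k] < order[k - 1]:
            draw = 0.5 * (float(order[k - 1]) + float(order[k]))
        else:
            draw = float(order[k - 1]) - max(abs(level), 1e-300) * 1e-9
        polys = _rings_at_level(grid, draw)
        enclosed = float(_points_inside(polys, pts).mean()) if not polys.is_empty else 0.0
        if enclosed >= coverage:
            break
        k += 1
    return DensityContour(
        level=level, polygons=polys, enclosed_fraction=enclosed, n_cells=len(pts)
    )


def _points_inside(polys: MultiPolygon, pts: np.ndarray) -> np.ndarray:
    import shapely

    geom = polys.buffer(0)
    return shapely.intersects_xy(geom, pts[:, 0], pts[:, 1])


def demarcate(
    cells: pd.DataFrame,
    gene: str,
    condition: str | None = None,
    coverage: float = DEFAULT_COVERAGE,
    bandwidth: tuple[float, float] | None = None,
    grid_n: int = DEFAULT_GRID_N,
    use_all_cells: bool = False,
) -> list[DensityContour]:
    """Per-section hotspot demarcation for one gene.

    For every section (optionally restricted to one condition) the KDE is
    computed over that section's suprathreshold cells for ``gene``
    (``use_all_cells=True`` uses every cell, for background comparison)
    and the minimal covering superlevel set is extracted. Sections with
    fewer than two qualifying cells are skipped with a warning.
    """
    flag = f"supra_{gene}"
    if not use_all_cells and flag not in cells.columns:
        raise KeyError(f"cells lack {flag!r}; run classify_cells first")
    sub = cells if condition is None else cells[cells["condition"] == condition]
    contours: list[DensityContour] = []
    for section_id, sec in sub.groupby("section_id", sort=True):
        sel = sec if use_all_cells else sec[sec[flag]]
        if len(sel) < 2:
            logger.warning(
                "section %s: %d suprathreshold cells for %s; skipped",
                section_id, len(sel), gene,
            )
            continue
        pts = sel[["x", "y"]].to_numpy()
        grid = kde2d(pts, bandwidth=bandwidth, grid_n=grid_n)
        contour = top_density_region(grid, pts, coverage)
        contour.gene = gene
        contour.condition = str(sec["condition"].iloc[0])
        contour.section_id = str(section_id)
        if not contour.polygons.is_empty:
            inside = _points_inside(contour.polygons, pts)
            if inside.any():
                contour.mean_puncta = float(sel[gene].to_numpy()[inside].mean())
        contours.append(contour)
    return contours
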