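"""Space-use metrics: daily travel, movement extent, and kernel home range.

Three complementary measures describe how much space a tracked animal uses:

* daily travel — cumulative distance between the day's relocations; a
  mobility proxy that ignores spatial extent;
* movement extent — the minimum convex polygon (MCP) over all relocations
  (area) and the maximum pairwise distance between them (linear extent);
  captures rare excursions but overestimates familiar area;
* home range — the area inside the 95% contour of a kernel-estimated
  utilization distribution (UD); the area the animal routinely occupies.

The UD uses a Gaussian product kernel with a per-axis two-stage direct
plug-in bandwidth (the Sheather-Jones/Wand-Jones family), the conservative
data-driven choice standard in home-range work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Polygon
from skimage import measure

from .core import Fix, SpaceUseSummary, Trajectory, as_points

_SQRT_PI = math.sqrt(math.pi)


@dataclass
class KDEConfig:
    """Kernel UD settings.

    bandwidth_method
        ``plugin`` (two-stage direct plug-in, default) or ``silverman``
        (normal-reference rule).
    grid_cells
        Evaluation grid resolution per axis (the UD area is a superlevel
        cell count times cell area, so resolution bounds area error).
    grid_pad
        Grid margin beyond the data range, in multiples of the larger
        bandwidth; 3 keeps >99.9% of kernel mass on the grid.
    ud_level
        Utilization fraction of the contour (0.95 = 95% UD home range).
    bandwidth
        Optional explicit (h_x, h_y) override; bypasses the selector.
    """

    bandwidth_method: str = "plugin"
    grid_cells: int = 256
    grid_pad: float = 3.0
    ud_level: float = 0.95
    bandwidth: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 < self.ud_level < 1:
            raise ValueError("ud_level must lie in (0, 1)")
        if self.grid_cells < 64:
            raise ValueError("grid_cells must be >= 64")
        if self.bandwidth_method not in ("plugin", "silverman"):
            raise ValueError(f"unknown bandwidth_method "
                             f"{self.bandwidth_method!r}")


def daily_travel(day_fixes: Sequence[Fix]) -> float:
    """Cumulative Euclidean distance over one calendar day's fixes.

    Zero for a single fix; raises if the fixes span more than one day.
    """
    if len(day_fixes) == 0:
        raise ValueError("no fixes")
    days = {f.t.date() for f in day_fixes}
    if len(days) > 1:
        raise ValueError(f"fixes span multiple days: {sorted(days)}")
    ordered = sorted(day_fixes, key=lambda f: f.t)
    return float(sum(a.distance_to(b) for a, b in zip(ordered, ordered[1:])))


def movement_extent_mcp(fixes: Sequence[Fix]
                        ) -> tuple[Polygon, float, bool]:
    """Minimum convex polygon of 100% of the fixes.

    Returns ``(hull, area_m2, degenerate)``; collinear or coincident point
    sets yield area 0 with the degenerate flag set.
    """
    pts = as_points(fixes)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if isinstance(hull, Polygon):
        return hull, float(hull.area), False
    # point or line string: zero-area degenerate hull
    return hull, 0.0, True


def movement_extent_distance(fixes: Sequence[Fix]) -> Optional[float]:
    """Maximum pairwise Euclidean distance between an animal's locations.

    Computed as the diameter of the convex hull (the diameter is always
    realized between hull vertices).  None for fewer than two fixes.
    """
    if len(fixes) < 2:
        return None
    pts = as_points(fixes)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    verts = np.asarray(hull.exterior.coords if isinstance(hull, Polygon)
                       else hull.coords, dtype=float)
    d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# Plug-in bandwidth selection (two-stage direct plug-in, Gaussian kernel)
# ---------------------------------------------------------------------------

def _phi_deriv(u: np.ndarray, r: int) -> np.ndarray:
    """r-th derivative of the standard normal density via Hermite
    polynomials: phi^(r)(u) = (-1)^r He_r(u) phi(u)."""
    he = np.polynomial.hermite_e.hermeval(u, [0.0] * r + [1.0])
    return (-1) ** r * he * np.exp(-0.5 * u * u) / math.sqrt(2 * math.pi)


def _psi_functional(x: np.ndarray, r: int, g: float) -> float:
    """Kernel estimator of the density functional psi_r = E f^(r)(X):
    n^-2 sum_ij phi^(r)((Xi-Xj)/g) / g^(r+1)."""
    n = len(x)
    diff = (x[:, None] - x[None, :]) / g
    return float(_phi_deriv(diff, r).sum() / (n * n * g ** (r + 1)))


def _psi_normal_reference(r: int, sigma: float) -> float:
    """psi_r for a N(0, sigma^2) density (r even):
    (-1)^(r/2) r! / ((2 sigma)^(r+1) (r/2)! sqrt(pi))."""
    return ((-1) ** (r // 2) * math.factorial(r)
            / ((2 * sigma) ** (r + 1) * math.factorial(r // 2) * _SQRT_PI))


def _dpi_bandwidth_1d(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for one axis.

    Stage 0 seeds psi_8 with the normal reference at the sample scale;
    stages 1-2 estimate psi_6 and psi_4 with kernel functional estimators
    at their own optimal pilot bandwidths; the AMISE-optimal h for the
    Gaussian kernel then follows from psi_4.
    """
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("zero variance on an axis: jitter the data or use "
                         "MCP-only analysis")
    psi8 = _psi_normal_reference(8, scale)
    # phi^(6)(0) = -15/sqrt(2 pi); phi^(4)(0) = 3/sqrt(2 pi)
    k6_0 = -15.0 / math.sqrt(2 * math.pi)
    k4_0 = 3.0 / math.sqrt(2 * math.pi)
    g1 = (-2.0 * k6_0 / (psi8 * n)) ** (1.0 / 9.0)
    psi6 = _psi_functional(x, 6, g1)
    g2 = (-2.0 * k4_0 / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_functional(x, 4, g2)
    # h = [R(K) / (mu2(K)^2 psi4 n)]^(1/5), Gaussian: R(K)=1/(2 sqrt(pi)),
    # mu2(K)=1
    return (1.0 / (2.0 * _SQRT_PI * psi4 * n)) ** 0.2


def _silverman_bandwidth_1d(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("zero variance on an axis: jitter the data or use "
                         "MCP-only analysis")
    return 0.9 * scale * n ** -0.2


def plugin_bandwidth(points: np.ndarray,
                     method: str = "plugin") -> tuple[float, float]:
    """Per-axis bandwidth vector (h_x, h_y) for the Gaussian product kernel.

    ``method='plugin'`` gives the two-stage direct plug-in selector;
    ``'silverman'`` the normal-reference rule.  Requires n >= 8 and nonzero
    variance on both axes.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 8:
        raise ValueError(f"need at least 8 points, got {len(pts)}")
    f = _dpi_bandwidth_1d if method == "plugin" else _silverman_bandwidth_1d
    return (f(pts[:, 0]), f(pts[:, 1]))


# ---------------------------------------------------------------------------
# Kernel utilization distribution
# ---------------------------------------------------------------------------

@dataclass
class HomeRange:
    """Result of a kernel-UD home-range estimate."""

    area_m2: float
    level: float
    bandwidth: tuple[float, float]
    threshold: float          # density threshold of the superlevel set
    polygons: list[Polygon] = field(default_factory=list)
    grid_x: Optional[np.ndarray] = None
    grid_y: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None


def home_range_ud(fixes: Sequence[Fix] | np.ndarray,
                  cfg: Optional[KDEConfig] = None) -> HomeRange:
    """Home range as the area inside the ``ud_level`` UD contour.

    A Gaussian product-kernel density is evaluated on a padded regular
    grid; the contour threshold is the largest density value whose
    superlevel set holds at least ``ud_level`` of the total grid mass, and
    the area is the superlevel cell count times the cell area.  Contour
    polygons (at the threshold) are returned for export.
    """
    cfg = cfg or KDEConfig()
    pts = (np.asarray(fixes, dtype=float) if isinstance(fixes, np.ndarray)
           else as_points(fixes))
    hx, hy = (cfg.bandwidth if cfg.bandwidth is not None
              else plugin_bandwidth(pts, cfg.bandwidth_method))

    pad = cfg.grid_pad * max(hx, hy)
    gx = np.linspace(pts[:, 0].min() - pad, pts[:, 0].max() + pad,
                     cfg.grid_cells)
    gy = np.linspace(pts[:, 1].min() - pad, pts[:, 1].max() + pad,
                     cfg.grid_cells)
    # separable Gaussian product kernel: density = Kx @ Ky^T / n
    ux = (gx[:, None] - pts[None, :, 0]) / hx
    uy = (gy[:, None] - pts[None, :, 1]) / hy
    kx = np.exp(-0.5 * ux * ux) / (hx * math.sqrt(2 * math.pi))
    ky = np.exp(-0.5 * uy * uy) / (hy * math.sqrt(2 * math.pi))
    dens = kx @ ky.T / len(pts)          # shape (nx, ny)

    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(dens.ravel())[::-1]
    mass = np.cumsum(flat) * cell_area
    total = mass[-1]
    k = int(np.searchsorted(mass, cfg.ud_level * total) + 1)
    k = min(k, flat.size)
    threshold = float(flat[k - 1])
    area = float(k * cell_area)

    polygons = []
    for contour in measure.find_contours(dens, threshold):
        xs = np.interp(contour[:, 0], np.arange(len(gx)), gx)
        ys = np.interp(contour[:, 1], np.arange(len(gy)), gy)
        if len(xs) >= 4:
            poly = Polygon(np.column_stack([xs, ys]))
            if poly.is_valid and poly.area > 0:
                polygons.append(poly)

    return HomeRange(area_m2=area, level=cfg.ud_level, bandwidth=(hx, hy),
                     threshold=threshold, polygons=polygons,
                     grid_x=gx, grid_y=gy, density=dens)


def percent_difference(group_a_mean: float, group_b_mean: float) -> float:
    """Signed percent difference 100 * (a - b) / b on the natural scale.

    Group means of log-transformed variables should be back-transformed
    (exponentiated) before calling, so the result reads "a is X% larger
    than b".
    """
    if group_b_mean <= 0:
        raise ValueError("reference mean must be positive")
    if group_a_mean <= 0:
        raise ValueError("group mean must be positive")
    return 100.0 * (group_a_mean - group_b_mean) / group_b_mean


def summarize_space_use(traj: Trajectory,
                        kde: Optional[KDEConfig] = None,
                        min_days_for_range: int = 7) -> SpaceUseSummary:
    """All space-use metrics for one (already downsampled) trajectory.

    Extent and home range are reported only for animals tracked at least
    ``min_days_for_range`` distinct days; daily travel always.
    """
    days = traj.split_days()
    travels = [daily_travel(v) for v in days.values()]
    summary = SpaceUseSummary(
        animal_id=traj.animal_id,
        days_tracked=len(days),
        daily_travel_mean_m=float(np.mean(travels)),
        species=traj.species, sex=traj.sex)
    if len(days) >= min_days_for_range:
        _, area, _ = movement_extent_mcp(traj.fixes)
        summary.extent_area_m2 = area
        summary.extent_distance_m = movement_extent_distance(traj.fixes)
        if len(traj.fixes) >= 8:
            try:
                summary.home_range_m2 = home_range_ud(traj.fixes, kde).area_m2
            except ValueError:
                summary.home_range_m2 = None
    return summary
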