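"""Translocation-experiment metrics.

An animal displaced from its home area is tracked after release; these
functions quantify whether and how it returned:

* homing success — did it cover at least 70% of the release-to-home-center
  distance within the class-specific window (3 days for ~50 m, 6 for
  ~200 m)?
* explored area — union of 5 m perceptual-range buffers around the
  post-release path;
* straightness — net displacement over cumulative path length of the
  homing trajectory, truncated at arrival;
* angular deviation — signed error between the initial movement direction
  (at a distance band scaled to ~20% of the translocation distance) and
  the true home direction;
* homing duration — day-time hours from release to crossing a 10 m buffer
  around the home polygon (the study animals do not move at night, so each
  complete night subtracts a fixed 12 h block).

Homing success is evaluated on the full-resolution track; explored area
and straightness on the track downsampled to a 15-min minimum interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Literal, Optional

import numpy as np
from shapely.geometry import LineString, Point

from .core import (DistanceClass, Fix, NavSummary, TranslocationRecord,
                   Trajectory)
from .preprocess import downsample_min_interval


@dataclass
class NavConfig:
    """Navigation-metric settings.

    homing_fraction
        Fraction of the translocation distance that must be covered for a
        "homing" verdict (0.70: the animal approached within 30% of the
        release-to-home distance).
    perceptual_radius_m
        Buffer radius for explored area (putative perceptual range, 5 m).
    band_by_class
        (center, halfwidth) of the angular-deviation measurement annulus
        per distance class, in meters from the release site; the centers
        sit at ~20% of the translocation distance.
    home_buffer_m
        Dilation of the home polygon defining "arrived" (10 m).
    night_window / night_hours
        Fixed nightly inactivity block excluded from homing duration.
    band_mode
        ``fix``: the deviation is measured at the first recorded fix whose
        release distance falls inside the annulus (a step jumping clean
        across the annulus is interpolated at the center radius);
        ``interp``: always interpolate the crossing of the center-radius
        circle.
    """

    homing_fraction: float = 0.70
    perceptual_radius_m: float = 5.0
    nav_min_interval_min: float = 15.0
    band_by_class: dict = field(default_factory=lambda: {
        DistanceClass.D50: (10.0, 5.0),
        DistanceClass.D200: (40.0, 20.0)})
    home_buffer_m: float = 10.0
    night_hours: float = 12.0
    night_start: time = time(18, 0)
    night_end: time = time(6, 0)
    band_mode: Literal["fix", "interp"] = "fix"
    buffer_resolution: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.homing_fraction < 1:
            raise ValueError("homing_fraction must lie in (0, 1)")
        for cls, (c, hw) in self.band_by_class.items():
            if hw >= c:
                raise ValueError(f"band for {cls}: halfwidth {hw} must be "
                                 f"smaller than center {c}")


def homing_success(rec: TranslocationRecord,
                   cfg: Optional[NavConfig] = None) -> bool:
    """True iff some fix within the evaluation window approaches the home
    center to within (1 - homing_fraction) of the translocation distance.

    Uses the full-resolution track; the window boundary is inclusive.
    """
    cfg = cfg or NavConfig()
    d0 = rec.translocation_distance
    if d0 == 0:
        raise ValueError("release point coincides with home center")
    allowed = (1.0 - cfg.homing_fraction) * d0
    end = rec.window_end()
    hc = rec.home.center
    return any(f.t <= end and f.distance_to(hc) <= allowed
               for f in rec.track.fixes)


def explored_area(track: Trajectory, cfg: Optional[NavConfig] = None
                  ) -> float:
    """Area of the union of perceptual-range buffers around the path.

    The track is first downsampled to the 15-min navigation interval; the
    area is the union of round-capped buffers around every segment (a
    single fix yields the point-buffer disc, pi r^2).
    """
    cfg = cfg or NavConfig()
    ds = downsample_min_interval(track, cfg.nav_min_interval_min)
    xy = ds.coords()
    geom = Point(xy[0]) if len(xy) == 1 else LineString(xy)
    return float(geom.buffer(cfg.perceptual_radius_m,
                             quad_segs=cfg.buffer_resolution).area)


def _truncate_at_home(rec: TranslocationRecord, track: Trajectory,
                      cfg: NavConfig) -> Optional[list[tuple[float, float]]]:
    """Polyline from release to the first entry into the buffered home
    polygon, with the entering step clipped at the boundary.  None if the
    track never enters the buffer."""
    buf = rec.home.buffered(cfg.home_buffer_m)
    pts = [rec.release_point] + [f.xy for f in track.fixes]
    out = [pts[0]]
    if buf.covers(Point(pts[0])):
        return out
    for a, b in zip(pts, pts[1:]):
        if buf.covers(Point(b)):
            seg = LineString([a, b])
            inter = seg.intersection(buf.exterior)
            if not inter.is_empty:
                p = inter if inter.geom_type == "Point" else list(
                    inter.geoms)[0]
                out.append((p.x, p.y))
            else:
                out.append(b)
            return out
        out.append(b)
    return None


def straightness(rec: TranslocationRecord,
                 cfg: Optional[NavConfig] = None) -> Optional[float]:
    """Net-over-path straightness of the homing trajectory in (0, 1].

    The trajectory is downsampled to the navigation interval and truncated
    at the first entry into the home buffer, so the "end" is the arrival
    point rather than post-arrival wandering (tracks that never cross the
    buffer keep their full extent).  None when the path length is zero.
    """
    cfg = cfg or NavConfig()
    ds = downsample_min_interval(rec.track, cfg.nav_min_interval_min)
    poly = _truncate_at_home(rec, ds, cfg)
    if poly is None:
        poly = [rec.release_point] + [f.xy for f in ds.fixes]
    xy = np.asarray(poly, dtype=float)
    steps = np.hypot(*np.diff(xy, axis=0).T)
    path = float(steps.sum())
    if path == 0:
        return None
    net = float(np.hypot(*(xy[-1] - xy[0])))
    return min(net / path, 1.0)


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def bearing(origin: tuple[float, float], target: tuple[float, float]
            ) -> float:
    """Planar bearing (radians, atan2 convention) from origin to target."""
    return math.atan2(target[1] - origin[1], target[0] - origin[0])


def angular_deviation(rec: TranslocationRecord,
                      cfg: Optional[NavConfig] = None
                      ) -> tuple[Optional[float], bool]:
    """Signed angular error of the initial orientation, in (-pi, pi].

    Finds the first point where the track crosses the class-specific
    annulus around the release site and returns the wrapped difference
    between the bearing release->point and the bearing release->home
    center.  Returns ``(None, False)`` if the animal never reaches the
    annulus' inner radius.  The second element flags whether the point was
    obtained by interpolating a step that jumped clean across the annulus.
    """
    cfg = cfg or NavConfig()
    center, halfwidth = cfg.band_by_class[rec.distance_class]
    lo, hi = center - halfwidth, center + halfwidth
    rp = rec.release_point
    home_bearing = bearing(rp, rec.home.center)

    prev = rp
    prev_d = 0.0
    for f in rec.track.fixes:
        d = f.distance_to(rp)
        crossing_radius = None
        if cfg.band_mode == "interp" and prev_d < center <= d:
            crossing_radius = center
        elif cfg.band_mode == "fix":
            if lo <= d <= hi:
                ang = _wrap_angle(bearing(rp, f.xy) - home_bearing)
                return ang, False
            if prev_d < lo and d > hi:
                crossing_radius = center   # jumped across the whole band
        if crossing_radius is not None:
            p = _circle_crossing(prev, f.xy, rp, crossing_radius)
            ang = _wrap_angle(bearing(rp, p) - home_bearing)
            return ang, True
        prev, prev_d = f.xy, d
    return None, False


def _circle_crossing(a: tuple[float, float], b: tuple[float, float],
                     center: tuple[float, float], radius: float
                     ) -> tuple[float, float]:
    """First intersection of segment a->b with the circle |p - center| = r.

    Assumes a inside and b outside (|a-c| < r <= |b-c|)."""
    ax, ay = a[0] - center[0], a[1] - center[1]
    dx, dy = b[0] - a[0], b[1] - a[1]
    A = dx * dx + dy * dy
    B = 2 * (ax * dx + ay * dy)
    C = ax * ax + ay * ay - radius * radius
    disc = max(B * B - 4 * A * C, 0.0)
    t = (-B + math.sqrt(disc)) / (2 * A)
    t = min(max(t, 0.0), 1.0)
    return (a[0] + t * dx, a[1] + t * dy)


def _count_complete_nights(start: datetime, end: datetime,
                           cfg: NavConfig) -> int:
    """Number of whole night blocks (night_start -> next-day night_end)
    fully contained in [start, end]."""
    n = 0
    d = start.date()
    while True:
        night_from = datetime.combine(d, cfg.night_start)
        night_to = datetime.combine(d + timedelta(days=1), cfg.night_end)
        if night_from >= end:
            break
        if night_from >= start and night_to <= end:
            n += 1
        d += timedelta(days=1)
    return n


def homing_duration(rec: TranslocationRecord,
                    cfg: Optional[NavConfig] = None) -> float:
    """Day-time hours from release to crossing the buffered home polygon.

    The entry time interpolates the entering step linearly against the
    buffer boundary.  Each complete night between release and entry
    removes a fixed ``night_hours`` block; the result is clamped at zero.
    Raises if the track never enters the buffer (inconsistent with a
    homing=true verdict).
    """
    cfg = cfg or NavConfig()
    buf = rec.home.buffered(cfg.home_buffer_m)
    prev_xy, prev_t = rec.release_point, rec.release_time
    entry: Optional[datetime] = None
    for f in rec.track.fixes:
        if buf.covers(Point(f.xy)):
            seg = LineString([prev_xy, f.xy])
            inter = seg.intersection(buf.exterior)
            if inter.is_empty:
                entry = f.t
            else:
                p = inter if inter.geom_type == "Point" else list(
                    inter.geoms)[0]
                frac = (seg.project(p) / seg.length if seg.length > 0
                        else 0.0)
                entry = prev_t + frac * (f.t - prev_t)
            break
        prev_xy, prev_t = f.xy, f.t
    if entry is None:
        raise ValueError(f"{rec.animal_id}: no fix inside the home buffer; "
                         f"inputs inconsistent with homing")
    elapsed_h = (entry - rec.release_time).total_seconds() / 3600.0
    nights = _count_complete_nights(rec.release_time, entry, cfg)
    return max(elapsed_h - cfg.night_hours * nights, 0.0)


def normalize_homeward(rec: TranslocationRecord) -> Trajectory:
    """Rigidly transform the track to a common frame: the release point at
    the origin and the home direction along +y.  Distances are preserved.
    """
    d0 = rec.translocation_distance
    if d0 == 0:
        raise ValueError("release point coincides with home center")
    rx, ry = rec.release_point
    theta = bearing(rec.release_point, rec.home.center)
    rot = math.pi / 2 - theta   # map home bearing onto +y
    c, s = math.cos(rot), math.sin(rot)
    fixes = []
    for f in rec.track.fixes:
        dx, dy = f.x - rx, f.y - ry
        fixes.append(Fix(f.animal_id, f.t,
                         c * dx - s * dy, s * dx + c * dy,
                         f.behavior, f.source))
    return rec.track.replace_fixes(fixes)


def summarize_navigation(rec: TranslocationRecord,
                         cfg: Optional[NavConfig] = None) -> NavSummary:
    """All navigation metrics for one translocation, with the homing-only
    metrics (straightness, duration) left undefined for non-homing animals.
    """
    cfg = cfg or NavConfig()
    homed = homing_success(rec, cfg)
    area = explored_area(rec.track, cfg)
    dev, interpolated = angular_deviation(rec, cfg)
    if interpolated:
        warnings.warn(f"{rec.animal_id}: band crossing interpolated "
                      f"(sparse sampling near the annulus)")
    s = d = None
    if homed:
        s = straightness(rec, cfg)
        try:
            d = homing_duration(rec, cfg)
        except ValueError:
            # homed by the 70% criterion but never crossed the home buffer
            d = None
    if d is not None:
        speed = _max_speed(rec.track)
        if speed > 0:
            # distance the animal must cover before "arrival": release to
            # the farthest point of the buffered home boundary
            buf = rec.home.buffered(cfg.home_buffer_m)
            hc = rec.home.center
            reach = max(math.hypot(cx - hc[0], cy - hc[1])
                        for cx, cy in buf.exterior.coords)
            lower = max(rec.translocation_distance - reach, 0.0) / speed
            if d < lower - 1e-9:
                warnings.warn(
                    f"{rec.animal_id}: homing duration {d:.2f} h below the "
                    f"straight-line/maximum-speed bound {lower:.2f} h")
    return NavSummary(animal_id=rec.animal_id, homing=homed,
                      explored_area_m2=area, straightness=s,
                      angular_deviation_rad=dev, homing_duration_h=d,
                      species=rec.track.species, sex=rec.track.sex,
                      distance_class=rec.distance_class)


def _max_speed(track: Trajectory) -> float:
    """Maximum observed speed (m/h) between consecutive fixes."""
    best = 0.0
    for a, b in zip(track.fixes, track.fixes[1:]):
        dt_h = (b.t - a.t).total_seconds() / 3600.0
        if dt_h > 0:
            best = max(best, a.distance_to(b) / dt_h)
    return best
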