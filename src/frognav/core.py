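"""Domain types for tracked-animal relocation data.

Coordinates are planar (a local engineering frame, in meters); no geodesy
is performed anywhere in the package.  Timestamps are timezone-naive local
time and "days" break at local midnight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, date
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry


class Behavior(str, Enum):
    """Behavior annotation attached to a single relocation."""

    PARENTAL = "parental"
    MATING = "mating"
    OTHER = "other"
    UNKNOWN = "unknown"


class Species(str, Enum):
    """Study species codes.

    Af = Allobates femoralis (male care), Dt = Dendrobates tinctorius
    (male care), Os = Oophaga sylvatica (female care).
    """

    AF = "Af"
    DT = "Dt"
    OS = "Os"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class FixSource(str, Enum):
    TRACKING = "tracking"
    RECAPTURE = "recapture"


class DistanceClass(str, Enum):
    """Translocation distance class; binds the homing evaluation window."""

    D50 = "d50"
    D200 = "d200"


#: Homing evaluation window (days after release) per translocation distance.
WINDOW_DAYS = {DistanceClass.D50: 3, DistanceClass.D200: 6}


@dataclass(frozen=True)
class Fix:
    """One timestamped planar relocation of one animal."""

    animal_id: str
    t: datetime
    x: float
    y: float
    behavior: Behavior = Behavior.OTHER
    source: FixSource = FixSource.TRACKING

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.animal_id}: "
                             f"({self.x}, {self.y})")
        if self.t is None:
            raise ValueError("fix timestamp must be defined")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)

    def distance_to(self, other: "Fix | tuple[float, float]") -> float:
        ox, oy = (other.x, other.y) if isinstance(other, Fix) else other
        return math.hypot(self.x - ox, self.y - oy)


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal plus identity metadata."""

    animal_id: str
    fixes: tuple[Fix, ...]
    species: Optional[Species] = None
    sex: Optional[Sex] = None
    weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        self.fixes = tuple(self.fixes)
        if len(self.fixes) == 0:
            raise ValueError(f"trajectory {self.animal_id} has no fixes")
        for f in self.fixes:
            if f.animal_id != self.animal_id:
                raise ValueError(
                    f"fix animal_id {f.animal_id!r} != trajectory "
                    f"{self.animal_id!r}")
        for a, b in zip(self.fixes, self.fixes[1:]):
            if not a.t < b.t:
                raise ValueError(
                    f"fixes of {self.animal_id} not strictly increasing in "
                    f"time at {a.t}")
        if self.weight_g is not None and self.weight_g <= 0:
            raise ValueError("weight_g must be positive")

    def __len__(self) -> int:
        return len(self.fixes)

    def __iter__(self):
        return iter(self.fixes)

    def coords(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in fix order."""
        return np.array([[f.x, f.y] for f in self.fixes], dtype=float)

    def times(self) -> list[datetime]:
        return [f.t for f in self.fixes]

    def days_tracked(self) -> int:
        """Number of distinct calendar days with at least one fix."""
        return len({f.t.date() for f in self.fixes})

    def split_days(self) -> dict[date, list[Fix]]:
        """Fixes grouped by calendar day (local midnight boundaries)."""
        out: dict[date, list[Fix]] = {}
        for f in self.fixes:
            out.setdefault(f.t.date(), []).append(f)
        return out

    def path_length(self) -> float:
        """Cumulative Euclidean length of the polyline through all fixes."""
        if len(self.fixes) < 2:
            return 0.0
        xy = self.coords()
        return float(np.hypot(*(np.diff(xy, axis=0).T)).sum())

    def replace_fixes(self, fixes: Iterable[Fix]) -> "Trajectory":
        return Trajectory(self.animal_id, tuple(fixes), self.species,
                          self.sex, self.weight_g)


@dataclass
class DayRecord:
    """Per-animal per-day movement summary with a behavior-day label."""

    animal_id: str
    date: date
    day_type: Behavior
    daily_travel_m: float
    n_fixes: int
    daytime_temp_C: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_fixes < 1:
            raise ValueError("n_fixes must be >= 1")
        if self.daily_travel_m < 0:
            raise ValueError("daily_travel_m must be >= 0")
        if self.day_type not in (Behavior.PARENTAL, Behavior.MATING,
                                 Behavior.OTHER):
            raise ValueError(f"invalid day_type {self.day_type}")


@dataclass
class HomeArea:
    """Pre-translocation fix set, its hull, and its geometric-mean center.

    The center is the coordinate-wise arithmetic mean of the fixes ("the
    geometric average of frog positions prior to translocation"); the
    polygon is the convex hull, possibly degenerate (point or segment).
    """

    fixes: tuple[Fix, ...]
    center: tuple[float, float] = field(init=False)
    polygon: BaseGeometry = field(init=False)

    def __post_init__(self) -> None:
        self.fixes = tuple(self.fixes)
        if len(self.fixes) == 0:
            raise ValueError("home area requires at least one fix")
        xy = np.array([[f.x, f.y] for f in self.fixes], dtype=float)
        self.center = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        self.polygon = MultiPoint([tuple(p) for p in xy]).convex_hull

    @property
    def degenerate(self) -> bool:
        return not isinstance(self.polygon, Polygon)

    def buffered(self, radius_m: float) -> Polygon:
        """Home polygon dilated by ``radius_m`` (round joins)."""
        return self.polygon.buffer(radius_m)


@dataclass
class TranslocationRecord:
    """One translocation event with its post-release track."""

    animal_id: str
    release_point: tuple[float, float]
    release_time: datetime
    distance_class: DistanceClass
    home: HomeArea
    track: Trajectory
    window_days: Optional[int] = None

    def __post_init__(self) -> None:
        self.distance_class = DistanceClass(self.distance_class)
        if self.window_days is None:
            self.window_days = WINDOW_DAYS[self.distance_class]
        elif self.window_days != WINDOW_DAYS[self.distance_class]:
            raise ValueError(
                f"window_days={self.window_days} inconsistent with "
                f"{self.distance_class.value} "
                f"(expected {WINDOW_DAYS[self.distance_class]})")
        if self.track.fixes[0].t < self.release_time:
            raise ValueError("first track fix precedes release time")

    @property
    def translocation_distance(self) -> float:
        hx, hy = self.home.center
        rx, ry = self.release_point
        return math.hypot(hx - rx, hy - ry)

    def window_end(self) -> datetime:
        from datetime import timedelta
        return self.release_time + timedelta(days=self.window_days)


@dataclass
class NavSummary:
    """Per-animal navigation metrics from one translocation.

    ``straightness`` and ``homing_duration_h`` are defined only for animals
    that homed; ``angular_deviation_rad`` is undefined when the animal never
    reached the measurement band.  Spatial variables are exported on the
    natural scale; downstream models conventionally work on ln(area).
    """

    animal_id: str
    homing: bool
    explored_area_m2: float
    straightness: Optional[float] = None
    angular_deviation_rad: Optional[float] = None
    homing_duration_h: Optional[float] = None
    species: Optional[Species] = None
    sex: Optional[Sex] = None
    distance_class: Optional[DistanceClass] = None

    def __post_init__(self) -> None:
        if not self.homing:
            if self.straightness is not None:
                raise ValueError("straightness defined for non-homing animal")
            if self.homing_duration_h is not None:
                raise ValueError("duration defined for non-homing animal")
        if self.straightness is not None and not 0 < self.straightness <= 1:
            raise ValueError(f"straightness {self.straightness} not in (0,1]")
        if self.explored_area_m2 <= 0:
            raise ValueError("explored_area_m2 must be positive")


@dataclass
class SpaceUseSummary:
    """Per-animal space-use metrics ready for downstream statistics."""

    animal_id: str
    days_tracked: int
    daily_travel_mean_m: float
    extent_area_m2: Optional[float] = None
    extent_distance_m: Optional[float] = None
    home_range_m2: Optional[float] = None
    species: Optional[Species] = None
    sex: Optional[Sex] = None

    def __post_init__(self) -> None:
        for name in ("extent_area_m2", "home_range_m2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


def as_points(fixes: Sequence[Fix]) -> np.ndarray:
    """(n, 2) coordinate array from a fix sequence."""
    return np.array([[f.x, f.y] for f in fixes], dtype=float)
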