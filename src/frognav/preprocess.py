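"""Sampling-rate standardization, behavior-day labeling, and covariates.

Raw relocation data oversample behaviorally interesting movements (e.g.
tadpole transport), so spatial metrics computed from them are biased by
effort.  The two-step downsampling here standardizes every animal to a
sparse diurnal schedule (3-7 fixes/day, median 4) before any space-use
metric is computed: step 1 thins unusually dense days while protecting
rare-behavior fixes and temporal spread; step 2 enforces a minimum sampling
interval while keeping intermediate points of long, fast movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Behavior, DayRecord, Fix, Sex, Species, Trajectory

#: Behaviors protected from removal in downsampling step 1.
RARE_BEHAVIORS = frozenset({Behavior.PARENTAL, Behavior.MATING})


@dataclass
class DownsampleConfig:
    """Parameters of the two-step downsampling procedure.

    min_interval_min
        Step-2 minimum sampling interval (minutes).
    fast_move_m
        Step-2 retention distance: a fix closer in time than the minimum
        interval is still kept if it lies farther than this from the last
        kept fix (long, fast movements).
    daily_excess
        Step-1 trigger: days with more than ``daily mean + daily_excess``
        fixes get thinned.
    target_daily_range / target_daily_median
        Intended post-downsampling fixes per day.
    nav_min_interval_min
        Minimum interval used for translocation tracks (explored area and
        straightness), finer than the space-use interval.
    """

    min_interval_min: float = 60.0
    fast_move_m: float = 20.0
    daily_excess: int = 2
    target_daily_range: tuple[int, int] = (3, 7)
    target_daily_median: int = 4
    nav_min_interval_min: float = 15.0

    def __post_init__(self) -> None:
        if self.fast_move_m <= 0:
            raise ValueError("fast_move_m must be positive")
        if self.min_interval_min <= self.nav_min_interval_min:
            raise ValueError(
                "min_interval_min must exceed nav_min_interval_min")


def _thin_day_greedy(day_fixes: Sequence[Fix], target: int) -> list[Fix]:
    """Greedy step-1 thinning of one day's fixes.

    Always keeps the first and last fix of the day and every fix with a
    protected (parental/mating) behavior; then repeatedly adds the fix
    maximizing the minimum time gap to already-kept fixes until ``target``
    fixes are kept (earliest fix wins ties).
    """
    n = len(day_fixes)
    keep = {0, n - 1}
    keep.update(i for i, f in enumerate(day_fixes)
                if f.behavior in RARE_BEHAVIORS)
    while len(keep) < min(target, n):
        best_i, best_gap = None, -1.0
        for i in range(n):
            if i in keep:
                continue
            gap = min(abs((day_fixes[i].t - day_fixes[j].t).total_seconds())
                      for j in keep)
            if gap > best_gap:
                best_i, best_gap = i, gap
        keep.add(best_i)
    return [day_fixes[i] for i in sorted(keep)]


def downsample_step1(traj: Trajectory, cfg: DownsampleConfig,
                     dataset_daily_mean: Optional[float] = None,
                     log: Optional[list] = None) -> Trajectory:
    """Thin days whose fix count exceeds the dataset daily mean + excess."""
    days = traj.split_days()
    if dataset_daily_mean is None:
        dataset_daily_mean = float(np.mean([len(v) for v in days.values()]))
    threshold = dataset_daily_mean + cfg.daily_excess
    kept: list[Fix] = []
    for d in sorted(days):
        day_fixes = days[d]
        if len(day_fixes) > threshold:
            chosen = _thin_day_greedy(day_fixes, cfg.target_daily_median)
            if log is not None:
                dropped = [f for f in day_fixes if f not in chosen]
                log.append((traj.animal_id, d, len(day_fixes), len(chosen),
                            dropped))
            kept.extend(chosen)
        else:
            kept.extend(day_fixes)
    return traj.replace_fixes(kept)


def downsample_min_interval(traj: Trajectory, min_interval_min: float,
                            fast_move_m: Optional[float] = None) -> Trajectory:
    """Step-2 linear scan: keep a fix if it is at least ``min_interval_min``
    after the last kept fix, or (if ``fast_move_m`` is set) farther than
    ``fast_move_m`` from it.  The first fix is always kept."""
    kept = [traj.fixes[0]]
    min_dt = timedelta(minutes=min_interval_min)
    for f in traj.fixes[1:]:
        last = kept[-1]
        if f.t - last.t >= min_dt:
            kept.append(f)
        elif fast_move_m is not None and f.distance_to(last) > fast_move_m:
            kept.append(f)
    return traj.replace_fixes(kept)


def downsample_two_step(traj: Trajectory, cfg: Optional[DownsampleConfig]
                        = None, dataset_daily_mean: Optional[float] = None,
                        log: Optional[list] = None) -> Trajectory:
    """Full two-step downsampling; output fixes are a subset of the input."""
    cfg = cfg or DownsampleConfig()
    thinned = downsample_step1(traj, cfg, dataset_daily_mean, log)
    return downsample_min_interval(thinned, cfg.min_interval_min,
                                   cfg.fast_move_m)


@dataclass(frozen=True)
class Encounter:
    """Position of an opposite-sex individual on a given day."""

    date: date
    x: float
    y: float


#: (species, sex) pairs whose pool proximity does NOT count as parental
#: behavior (no parental care reported for O. sylvatica males).
DEFAULT_POOL_EXEMPT = frozenset({(Species.OS, Sex.MALE)})


def label_behavior_days(
    traj: Trajectory,
    pools: Sequence[tuple[float, float]] = (),
    encounters: Sequence[Encounter] = (),
    radius_m: float = 1.0,
    pool_exempt: frozenset = DEFAULT_POOL_EXEMPT,
    study_window: Optional[tuple[datetime, datetime]] = None,
) -> list[DayRecord]:
    """Categorize each tracking day as parental, mating, or other.

    A fix is parental if annotated so, or within ``radius_m`` of a known
    breeding pool (unless the animal's (species, sex) is pool-exempt); it
    is mating if annotated so, or within ``radius_m`` of a same-day
    opposite-sex encounter point.  A day is parental if it has at least one
    parental fix (parental overrides mating on conflict days, as parental
    movements are larger in scale), else mating if at least one mating fix,
    else other.  Daily travel is the cumulative Euclidean distance over the
    day's fixes in time order.
    """
    exempt = (traj.species, traj.sex) in pool_exempt
    fixes = traj.fixes
    if study_window is not None:
        lo, hi = study_window
        outside = [f for f in fixes if not lo <= f.t <= hi]
        if outside:
            warnings.warn(f"{len(outside)} fixes of {traj.animal_id} outside "
                          f"study window; excluded")
        fixes = [f for f in fixes if lo <= f.t <= hi]

    by_day: dict[date, list[Fix]] = {}
    for f in fixes:
        by_day.setdefault(f.t.date(), []).append(f)

    records: list[DayRecord] = []
    for d in sorted(by_day):
        day_fixes = by_day[d]
        parental = mating = False
        for f in day_fixes:
            if f.behavior is Behavior.PARENTAL:
                parental = True
            elif f.behavior is Behavior.MATING:
                mating = True
            if not parental and not exempt and any(
                    f.distance_to(p) <= radius_m for p in pools):
                parental = True
            if not mating and any(
                    e.date == d and f.distance_to((e.x, e.y)) <= radius_m
                    for e in encounters):
                mating = True
        day_type = (Behavior.PARENTAL if parental
                    else Behavior.MATING if mating else Behavior.OTHER)
        travel = sum(a.distance_to(b)
                     for a, b in zip(day_fixes, day_fixes[1:]))
        records.append(DayRecord(traj.animal_id, d, day_type,
                                 float(travel), len(day_fixes)))
    return records


DEFAULT_SUNRISE = time(6, 0)
DEFAULT_SUNSET = time(18, 0)


def daytime_temperature(log: pd.DataFrame, day: date,
                        sunrise: time = DEFAULT_SUNRISE,
                        sunset: time = DEFAULT_SUNSET) -> Optional[float]:
    """Mean of temperature readings between sunrise and sunset on ``day``.

    ``log`` needs columns ``t`` (timestamp) and ``temp_C``.  Returns None
    when no reading falls in the window (missing covariate).
    """
    lo = datetime.combine(day, sunrise)
    hi = datetime.combine(day, sunset)
    sel = log[(log["t"] >= lo) & (log["t"] <= hi)]
    if sel.empty:
        return None
    return float(sel["temp_C"].mean())


def tracking_daytime_temperature(
        log: pd.DataFrame, start: date, end: date,
        sunrise: time = DEFAULT_SUNRISE,
        sunset: time = DEFAULT_SUNSET) -> Optional[float]:
    """Mean daytime temperature over an animal's tracking period: the
    average of the per-day daytime means from ``start`` to ``end``
    inclusive, skipping days with no readings."""
    vals = []
    d = start
    while d <= end:
        v = daytime_temperature(log, d, sunrise, sunset)
        if v is not None:
            vals.append(v)
        d += timedelta(days=1)
    return float(np.mean(vals)) if vals else None


def recapture_extent(fixes: Sequence[Fix], min_gap_days: float = 30
                     ) -> tuple[Optional[float], Optional[float]]:
    """Maximum linear distance among capture points of one animal.

    Returns ``(max_distance_m, span_days)``.  The distance is defined only
    when the animal was recaptured at least ``min_gap_days`` apart (time
    span first to last capture); it is then the maximum pairwise Euclidean
    distance over ALL of the animal's capture points.
    """
    if len(fixes) < 2:
        return None, None
    ids = {f.animal_id for f in fixes}
    if len(ids) > 1:
        raise ValueError(f"fixes from multiple animals: {sorted(ids)}")
    ts = sorted(f.t for f in fixes)
    span_days = (ts[-1] - ts[0]).total_seconds() / 86400.0
    if span_days < min_gap_days:
        return None, span_days
    xy = np.array([[f.x, f.y] for f in fixes])
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max())), span_days
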