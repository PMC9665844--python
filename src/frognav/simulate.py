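"""Synthetic movement generator for pipeline testing.

Residents follow a discrete Ornstein-Uhlenbeck (site-fidelity) walk around
a home center: x_{t+1} = x_t + kappa (c - x_t) + eps with isotropic
Gaussian noise whose scale depends on the behavioral day type (parental
excursions to breeding pools are larger than mating-day movements).  The
latent path runs at a fixed cadence (default 48 steps/day) and is observed
through the irregular diurnal sampling the field protocol produces: 3-7
fixes per day (median 4), daytime only.

Translocated animals follow a biased correlated random walk switching
between three behavioral states: ``local`` (small isotropic steps near the
release site), ``explore`` (correlated wandering, von Mises turning
angles), and ``home`` (headings von Mises-concentrated on the true home
bearing); the walk is absorbed on reaching the home area.

All randomness flows through one injectable numpy Generator, so studies
are byte-reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .core import (Behavior, DistanceClass, Fix, HomeArea, Sex, Species,
                   TranslocationRecord, Trajectory, WINDOW_DAYS)

_EPOCH = datetime(2023, 1, 1)

#: fixes-per-day distribution: support 3-7 with median 4
_FIXES_PER_DAY = (3, 4, 5, 6, 7)
_FIXES_PER_DAY_P = (0.20, 0.35, 0.20, 0.15, 0.10)


@dataclass
class ResidentParams:
    """Resident (site-fidelity) movement parameters.

    kappa is the per-step pull toward the home center; the stationary
    per-axis sd of the walk is step_sd / sqrt(kappa (2 - kappa)).
    """

    home_center: tuple[float, float] = (0.0, 0.0)
    kappa: float = 0.15
    step_sd_m: dict = field(default_factory=lambda: {
        Behavior.OTHER: 2.0, Behavior.MATING: 1.2, Behavior.PARENTAL: 4.0})
    pool_sites: tuple = ((8.0, 5.0),)
    p_day_type: dict = field(default_factory=lambda: {
        Behavior.PARENTAL: 0.25, Behavior.MATING: 0.15,
        Behavior.OTHER: 0.60})
    day_steps: int = 48
    excursion_steps: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")
        if any(v <= 0 for v in self.step_sd_m.values()):
            raise ValueError("step_sd_m values must be positive")
        if abs(sum(self.p_day_type.values()) - 1) > 1e-9:
            raise ValueError("day-type probabilities must sum to 1")

    def sigma_stationary(self, day_type: Behavior = Behavior.OTHER) -> float:
        """Per-axis stationary sd of the constant-day-type walk."""
        s = self.step_sd_m[day_type]
        return s * math.sqrt(1.0 / (self.kappa * (2.0 - self.kappa)))


@dataclass
class HomingParams:
    """Translocation (biased correlated random walk) parameters.

    The state chain runs at ``step_cadence_min`` during daytime only;
    nights pass without movement.  ``p_state`` rows are per-step transition
    probabilities for (local, explore, home).
    """

    translocation_distance_m: float = 50.0
    p_state: np.ndarray = field(default_factory=lambda: np.array([
        [0.980, 0.017, 0.003],
        [0.015, 0.978, 0.007],
        [0.005, 0.045, 0.950]]))
    kappa_turn: float = 4.0
    kappa_home: float = 8.0
    step_mean_m: float = 1.0
    local_step_m: float = 0.2
    step_cadence_min: float = 5.0
    obs_interval_min: float = 20.0
    absorb_buffer_m: float = 1.0
    day_start: time = time(6, 0)
    day_end: time = time(18, 0)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.p_state = np.asarray(self.p_state, dtype=float)
        if self.p_state.shape != (3, 3) or not np.allclose(
                self.p_state.sum(axis=1), 1.0):
            raise ValueError("p_state must be 3x3 with rows summing to 1")
        if self.kappa_turn < 0 or self.kappa_home < 0:
            raise ValueError("von Mises concentrations must be >= 0")

    @property
    def distance_class(self) -> DistanceClass:
        return (DistanceClass.D50 if self.translocation_distance_m <= 125
                else DistanceClass.D200)


STATES = ("local", "explore", "home")


def _daytime_step_indices(day_steps: int) -> np.ndarray:
    """Latent step indices falling between 06:00 and 18:00."""
    hours = np.arange(day_steps) * 24.0 / day_steps
    return np.where((hours >= 6.0) & (hours < 18.0))[0]


def _sample_spaced(rng: np.random.Generator, m: int, n: int, gap: int = 2,
                   forced: Optional[int] = None) -> list[int]:
    """Sample up to n positions in range(m), pairwise >= gap apart
    (random sequential packing), optionally forcing one position in.

    The spacing mirrors the field protocol: relocations of one animal are
    at least an hour apart, so downsampling leaves the daily counts
    intact.
    """
    chosen = [] if forced is None else [int(forced)]
    cands = [i for i in range(m)
             if all(abs(i - c) >= gap for c in chosen)]
    while len(chosen) < n and cands:
        i = cands[int(rng.integers(len(cands)))]
        chosen.append(i)
        cands = [j for j in cands if abs(j - i) >= gap]
    return sorted(chosen)


def simulate_resident(params: ResidentParams, n_days: int,
                      rng: Optional[np.random.Generator] = None,
                      animal_id: str = "sim",
                      species: Optional[Species] = None,
                      sex: Optional[Sex] = None,
                      start_date: Optional[date] = None,
                      ) -> tuple[Trajectory, dict]:
    """Simulate a resident animal for ``n_days`` days.

    Returns the observed (irregularly sampled, diurnal) trajectory and a
    ground-truth dict with the full latent path (``latent``: (n, 2) array,
    ``latent_times``), the sampled day types, and the stationary sd.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    start = start_date or _EPOCH.date()
    cx, cy = params.home_center
    pos = np.array([cx, cy], dtype=float)
    step_h = 24.0 / params.day_steps
    day_idx = _daytime_step_indices(params.day_steps)

    types = list(params.p_day_type)
    probs = [params.p_day_type[t] for t in types]

    latent: list[np.ndarray] = []
    latent_times: list[datetime] = []
    day_types: list[Behavior] = []
    fixes: list[Fix] = []

    for d in range(n_days):
        day_type = types[rng.choice(len(types), p=probs)]
        day_types.append(day_type)
        sd = params.step_sd_m[day_type]
        day0 = datetime.combine(start + timedelta(days=d), time(0, 0))

        # parental days insert a pool round-trip: waypoints walk out to the
        # pool and back over 2m latent steps around midday
        excursion: dict[int, np.ndarray] = {}
        pool_step = None
        if day_type is Behavior.PARENTAL and params.pool_sites:
            pool = np.asarray(params.pool_sites[
                rng.integers(len(params.pool_sites))], dtype=float)
            offset = pool - np.array([cx, cy])
            m = params.excursion_steps
            mid = params.day_steps // 2
            for j in range(2 * m + 1):
                frac = 1.0 - abs(j - m) / m   # 0 -> 1 -> 0 triangle
                excursion[mid - m + j] = frac * offset
            pool_step = mid

        center = np.array([cx, cy])
        day_positions = np.empty((params.day_steps, 2))
        for k in range(params.day_steps):
            if k in excursion:
                target = center + excursion[k]
                if k == pool_step:
                    # at the pool itself (deposits tadpoles / feeds eggs)
                    pos = target + rng.normal(0.0, 0.2, size=2)
                else:
                    pos = pos + 0.8 * (target - pos) \
                        + rng.normal(0.0, 0.3, size=2)
            else:
                pos = pos + params.kappa * (center - pos) \
                    + rng.normal(0.0, sd, size=2)
            day_positions[k] = pos
            latent.append(pos.copy())
            latent_times.append(day0 + timedelta(hours=k * step_h))

        n_fix = int(rng.choice(_FIXES_PER_DAY, p=_FIXES_PER_DAY_P))
        n_fix = min(n_fix, len(day_idx))
        forced = None
        if pool_step is not None and pool_step in day_idx:
            forced = int(np.searchsorted(day_idx, pool_step))
        positions = _sample_spaced(rng, len(day_idx), n_fix, forced=forced)
        chosen = [int(day_idx[p]) for p in positions]
        mating_pick = (rng.integers(len(chosen))
                       if day_type is Behavior.MATING else -1)
        for j, k in enumerate(chosen):
            x, y = day_positions[k]
            behavior = Behavior.OTHER
            if day_type is Behavior.PARENTAL and any(
                    math.hypot(x - px, y - py) <= 1.0
                    for px, py in params.pool_sites):
                behavior = Behavior.PARENTAL
            elif j == mating_pick:
                behavior = Behavior.MATING
            fixes.append(Fix(animal_id, day0 + timedelta(hours=k * step_h),
                             float(x), float(y), behavior))

    traj = Trajectory(animal_id, tuple(fixes), species=species, sex=sex)
    truth = {
        "latent": np.asarray(latent),
        "latent_times": latent_times,
        "day_types": day_types,
        "sigma_stationary": params.sigma_stationary(Behavior.OTHER),
        "home_center": params.home_center,
    }
    return traj, truth


def _sample_vm(rng: np.random.Generator, mu: float, kappa: float) -> float:
    if kappa <= 0:
        return float(rng.uniform(-math.pi, math.pi))
    return float(rng.vonmises(mu, kappa))


def simulate_translocation(params: HomingParams, home: HomeArea,
                           rng: Optional[np.random.Generator] = None,
                           release_point: Optional[tuple[float, float]]
                           = None,
                           release_time: Optional[datetime] = None,
                           animal_id: str = "sim",
                           species: Optional[Species] = None,
                           sex: Optional[Sex] = None,
                           ) -> tuple[TranslocationRecord, dict]:
    """Simulate one translocation and its post-release track.

    The release point defaults to ``translocation_distance_m`` from the
    home center in a random direction.  Returns the record (with the
    observation-sampled track) and a truth dict holding the
    full-resolution track and the latent state sequence.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    hc = np.asarray(home.center)
    if release_point is None:
        ang = rng.uniform(-math.pi, math.pi)
        release_point = (float(hc[0] + params.translocation_distance_m
                               * math.cos(ang)),
                         float(hc[1] + params.translocation_distance_m
                               * math.sin(ang)))
    release_time = release_time or datetime.combine(_EPOCH.date(),
                                                    time(14, 0))
    window_days = WINDOW_DAYS[params.distance_class]
    end_time = release_time + timedelta(days=window_days)
    # absorb only when effectively back inside the home area: a frog that
    # reaches its home polygon stays (site fidelity), whereas stopping at
    # the field protocol's wider tracking cutoff would strand walkers
    # outside the homing criterion radius
    buf = home.buffered(params.absorb_buffer_m)
    # cheap pre-test radius: polygon-containment only checked when the
    # walker is near enough to the home center to possibly be inside
    hx, hy = float(hc[0]), float(hc[1])
    reach = max(math.hypot(c[0] - hx, c[1] - hy)
                for c in (buf.exterior.coords if hasattr(buf, "exterior")
                          else buf.coords))
    cum = np.cumsum(params.p_state, axis=1)

    px, py = float(release_point[0]), float(release_point[1])
    heading = rng.uniform(-math.pi, math.pi)
    state = 0    # local
    t = release_time
    dt = timedelta(minutes=params.step_cadence_min)

    full: list[Fix] = [Fix(animal_id, t, px, py)]
    states = [STATES[state]]
    absorbed = False

    while t < end_time and not absorbed:
        t = t + dt
        if not params.day_start <= t.time() < params.day_end:
            continue     # no movement at night
        state = int(np.searchsorted(cum[state], rng.random()))
        if state == 0:
            heading = rng.uniform(-math.pi, math.pi)
            step = params.local_step_m * rng.exponential()
        elif state == 1:
            heading = _sample_vm(rng, heading, params.kappa_turn)
            step = params.step_mean_m * rng.exponential()
        else:
            home_bearing = math.atan2(hy - py, hx - px)
            heading = _sample_vm(rng, home_bearing, params.kappa_home)
            step = params.step_mean_m * rng.exponential()
        px += step * math.cos(heading)
        py += step * math.sin(heading)
        full.append(Fix(animal_id, t, px, py))
        states.append(STATES[state])
        if math.hypot(px - hx, py - hy) <= reach and buf.covers(
                Point(px, py)):
            absorbed = True

    obs: list[Fix] = [full[0]]
    obs_dt = timedelta(minutes=params.obs_interval_min)
    for f in full[1:]:
        if f.t - obs[-1].t >= obs_dt:
            obs.append(f)
    if absorbed and obs[-1].t != full[-1].t:
        obs.append(full[-1])

    track = Trajectory(animal_id, tuple(obs), species=species, sex=sex)
    rec = TranslocationRecord(animal_id, release_point, release_time,
                              params.distance_class, home, track)
    truth = {"full_track": Trajectory(animal_id, tuple(full),
                                      species=species, sex=sex),
             "states": states, "absorbed": absorbed}
    return rec, truth


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A full synthetic dataset mirroring the field-study inputs."""

    trajectories: list[Trajectory]
    pools: list[tuple[float, float]]
    translocations: list[TranslocationRecord]
    temperature: pd.DataFrame
    truths: dict

    def write(self, out_dir) -> None:
        """Write the standard CSV input set consumed by the CLI."""
        from .io import write_fixes
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixes(self.trajectories, out / "fixes.csv")
        pd.DataFrame(self.pools, columns=["x", "y"]).to_csv(
            out / "pools.csv", index=False)
        rows = []
        for rec in self.translocations:
            rows.append({
                "animal_id": rec.animal_id,
                "release_x": repr(rec.release_point[0]),
                "release_y": repr(rec.release_point[1]),
                "release_time": rec.release_time.isoformat(),
                "distance_class": rec.distance_class.value,
            })
        pd.DataFrame(rows).to_csv(out / "translocations.csv", index=False)
        write_fixes([rec.track for rec in self.translocations],
                    out / "nav_fixes.csv")
        self.temperature.to_csv(out / "temperature.csv", index=False)


def _caring_sex(species: Species) -> Sex:
    """Sex providing parental care: male in Af and Dt, female in Os."""
    return Sex.FEMALE if species is Species.OS else Sex.MALE


def _resident_preset(scenario: str, species: Species, sex: Sex,
                     home_center, pools) -> ResidentParams:
    base = ResidentParams(home_center=home_center, pool_sites=pools)
    if scenario == "null":
        p = {Behavior.PARENTAL: 0.15, Behavior.MATING: 0.15,
             Behavior.OTHER: 0.70}
        return replace(base, p_day_type=p)
    if scenario != "paper-like":
        raise ValueError(f"unknown scenario {scenario!r}")
    if sex == _caring_sex(species):
        p = {Behavior.PARENTAL: 0.30, Behavior.MATING: 0.15,
             Behavior.OTHER: 0.55}
        sd = {Behavior.OTHER: 2.5, Behavior.MATING: 1.2,
              Behavior.PARENTAL: 4.0}
    else:
        p = {Behavior.PARENTAL: 0.05, Behavior.MATING: 0.20,
             Behavior.OTHER: 0.75}
        sd = {Behavior.OTHER: 1.5, Behavior.MATING: 1.2,
              Behavior.PARENTAL: 4.0}
    return replace(base, p_day_type=p, step_sd_m=sd)


def _homing_preset(scenario: str, sex: Sex, distance_m: float
                   ) -> HomingParams:
    base = HomingParams(translocation_distance_m=distance_m)
    if scenario == "paper-like" and sex is Sex.MALE:
        # males range more widely after translocation
        p = np.array([[0.950, 0.045, 0.005],
                      [0.013, 0.977, 0.010],
                      [0.005, 0.045, 0.950]])
        return replace(base, p_state=p)
    return base


def _temperature_log(n_days: int, rng: np.random.Generator) -> pd.DataFrame:
    """Half-hourly understory temperature with a diurnal cycle."""
    rows = []
    for d in range(n_days):
        for half_hour in range(48):
            t = datetime.combine(_EPOCH.date() + timedelta(days=d),
                                 time(0, 0)) + timedelta(minutes=30
                                                         * half_hour)
            hour = half_hour / 2.0
            temp = 25.0 + 3.0 * math.sin(math.pi * (hour - 8.0) / 12.0) \
                + rng.normal(0.0, 0.3)
            rows.append({"t": t.isoformat(), "temp_C": round(temp, 3)})
    return pd.DataFrame(rows)


def make_study(seed: int, n_per_group: int = 4, n_days: int = 12,
               scenario: str = "paper-like") -> SyntheticStudy:
    """Generate a complete deterministic synthetic study.

    ``n_per_group`` animals per species x sex cell are simulated as
    residents for ``n_days`` days on a grid of home centers; each animal
    is then translocated once (alternating 50 m / 200 m).  Scenario
    ``paper-like`` makes the caring sex range wider day-to-day and males
    more explorative after translocation; ``null`` removes all sex
    differences.
    """
    rng = np.random.default_rng(seed)
    trajectories: list[Trajectory] = []
    translocations: list[TranslocationRecord] = []
    truths: dict = {"resident": {}, "translocation": {}}
    pools_all: list[tuple[float, float]] = []

    idx = 0
    for species in Species:
        for sex in Sex:
            for j in range(n_per_group):
                aid = f"{species.value}-{sex.value[0]}{j:02d}"
                gx, gy = (idx % 6) * 60.0, (idx // 6) * 60.0
                idx += 1
                pools = ((gx + 8.0, gy + 5.0),)
                pools_all.extend(pools)
                rp = _resident_preset(scenario, species, sex,
                                      (gx, gy), pools)
                traj, truth = simulate_resident(
                    rp, n_days, rng, animal_id=aid, species=species,
                    sex=sex)
                trajectories.append(traj)
                truths["resident"][aid] = truth

                dist = 50.0 if j % 2 == 0 else 200.0
                hp = _homing_preset(scenario, sex, dist)
                home = HomeArea(traj.fixes)
                release_time = datetime.combine(
                    _EPOCH.date() + timedelta(days=n_days), time(14, 0))
                rec, ttruth = simulate_translocation(
                    hp, home, rng, release_time=release_time,
                    animal_id=aid, species=species, sex=sex)
                translocations.append(rec)
                truths["translocation"][aid] = ttruth

    temperature = _temperature_log(n_days + 7, rng)
    return SyntheticStudy(trajectories, pools_all, translocations,
                          temperature, truths)
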