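from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frognav.core import (Behavior, DistanceClass, Fix, HomeArea,
                          TranslocationRecord, Trajectory)

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def fix(animal_id, t, x, y, behavior=Behavior.OTHER):
    """Shorthand fix constructor; t is an ISO string or datetime."""
    if isinstance(t, str):
        t = datetime.fromisoformat(t)
    return Fix(animal_id, t, float(x), float(y), behavior)


def traj(points, animal_id="a", t0=datetime(2023, 1, 1, 8, 0),
         step_min=60, **kw):
    """Trajectory through (x, y) points at a fixed sampling interval."""
    fixes = tuple(Fix(animal_id, t0 + timedelta(minutes=i * step_min),
                      float(x), float(y))
                  for i, (x, y) in enumerate(points))
    return Trajectory(animal_id, fixes, **kw)


def square_home(center=(50.0, 0.0), half=2.0, animal_id="a"):
    """Home area from four fixes on a square around ``center``."""
    cx, cy = center
    pts = [(cx - half, cy - half), (cx + half, cy - half),
           (cx + half, cy + half), (cx - half, cy + half)]
    t0 = datetime(2022, 12, 20, 8, 0)
    return HomeArea(tuple(
        Fix(animal_id, t0 + timedelta(hours=i), x, y)
        for i, (x, y) in enumerate(pts)))


def translocation(track_points, home_center=(50.0, 0.0),
                  release=(0.0, 0.0), step_min=60,
                  release_time=datetime(2023, 1, 1, 12, 0),
                  distance_class=DistanceClass.D50, animal_id="a"):
    """Translocation record with a track through ``track_points``."""
    home = square_home(home_center, animal_id=animal_id)
    fixes = tuple(Fix(animal_id,
                      release_time + timedelta(minutes=(i + 1) * step_min),
                      float(x), float(y))
                  for i, (x, y) in enumerate(track_points))
    track = Trajectory(animal_id, fixes)
    return TranslocationRecord(animal_id, release, release_time,
                               distance_class, home, track)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230101)


@pytest.fixture(scope="session")
def small_study():
    from frognav.simulate import make_study
    return make_study(7, n_per_group=2, n_days=10)
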