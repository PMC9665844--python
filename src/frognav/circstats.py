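"""Directed circular statistics for orientation data.

Angular deviations from the home direction live on the circle, so their
analysis needs circular tools: the resultant-vector summary, the V-test
(Rayleigh test against the alternative of clustering around a specified
direction — here, home), and a two-group comparison of circular
distributions via a MANOVA on the trigonometric components (cos, sin) of
each angle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class AngleSample:
    """A sample of wrapped angles with its expected (home) direction."""

    angles: np.ndarray
    mu_home: float = 0.0
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.angles.size < 1:
            raise ValueError("need at least one angle")
        self.angles = wrap_angles(self.angles)


def wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(a, dtype=float) + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def circular_summary(angles: Sequence[float]
                     ) -> tuple[Optional[float], float]:
    """Mean direction and mean resultant length of an angle sample.

    Returns ``(theta_bar, r)`` with theta_bar = atan2(mean sin, mean cos)
    and r in [0, 1].  When r is (numerically) zero the mean direction is
    undefined and None is returned for it.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle sample")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = float(math.hypot(c, s))
    if r < 1e-12:
        return None, r
    return float(math.atan2(s, c)), r


def rayleigh_homeward(angles: Sequence[float], mu_home: float = 0.0,
                      method: str = "asymptotic", n_sims: int = 10000,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[float, float]:
    """V-test: circular uniformity against clustering around ``mu_home``.

    The statistic is V = r cos(theta_bar - mu_home), the component of the
    mean resultant vector along the expected direction.  The asymptotic
    one-sided p comes from the standard-normal upper tail of
    u = V sqrt(2 n); a seeded Monte-Carlo p (uniform resampling) is
    available and is forced, with a warning, for n < 5.

    Returns ``(V, p)``.
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    n = a.size
    theta, r = circular_summary(a)
    v = 0.0 if theta is None else r * math.cos(theta - mu_home)
    if n < 5 and method == "asymptotic":
        warnings.warn("n < 5: asymptotic V-test unreliable, using "
                      "Monte-Carlo p-value")
        method = "montecarlo"
    if method == "asymptotic":
        u = v * math.sqrt(2 * n)
        p = float(stats.norm.sf(u))
    elif method == "montecarlo":
        rng = rng or np.random.default_rng()
        sims = rng.uniform(-np.pi, np.pi, size=(n_sims, n))
        c = np.cos(sims - mu_home).mean(axis=1)   # V* = mean cos(theta - mu)
        p = float((1 + np.sum(c >= v)) / (n_sims + 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(v), p


def trig_group_test(angles_a: Sequence[float], angles_b: Sequence[float],
                    statistic: str = "wilks"
                    ) -> tuple[float, tuple[int, int], float]:
    """Two-group comparison of circular distributions.

    Each angle maps to its trigonometric components (cos, sin); the groups
    are compared with a one-way MANOVA on that bivariate response.  For
    two groups and two responses Wilks' lambda has an exact F transform
    (equivalent to Hotelling's T-squared):

        F = (N - 3)/2 * (1 - Lambda)/Lambda,  df = (2, N - 3).

    Pillai's trace is available via ``statistic='pillai'`` (identical F
    for two groups).  Returns ``(F, (df1, df2), p)``.
    """
    a = np.atleast_1d(np.asarray(angles_a, dtype=float))
    b = np.atleast_1d(np.asarray(angles_b, dtype=float))
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 angles")
    if statistic not in ("wilks", "pillai"):
        raise ValueError(f"unknown statistic {statistic!r}")

    ya = np.column_stack([np.cos(a), np.sin(a)])
    yb = np.column_stack([np.cos(b), np.sin(b)])
    for name, y in (("a", ya), ("b", yb)):
        if np.allclose(y.var(axis=0), 0):
            raise ValueError(f"group {name} has zero variance in both "
                             f"trigonometric components")
    y = np.vstack([ya, yb])
    n = y.shape[0]
    grand = y.mean(axis=0)
    e = np.zeros((2, 2))
    h = np.zeros((2, 2))
    for yg in (ya, yb):
        mu = yg.mean(axis=0)
        d = yg - mu
        e += d.T @ d
        m = (mu - grand)[:, None]
        h += yg.shape[0] * (m @ m.T)
    lam = float(np.linalg.det(e) / np.linalg.det(e + h))
    df1, df2 = 2, n - 3
    if df2 <= 0:
        raise ValueError("too few observations for the exact F transform")
    f_stat = (df2 / df1) * (1 - lam) / lam
    p = float(stats.f.sf(f_stat, df1, df2))
    return f_stat, (df1, df2), p


def rayleigh_uniformity(angles: Sequence[float]) -> tuple[float, float]:
    """Plain (undirected) Rayleigh test of circular uniformity.

    Returns ``(r, p)`` with the standard small-sample-corrected p-value
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)).
    """
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    n = a.size
    _, r = circular_summary(a)
    big_r = n * r
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - big_r * big_r))
                 - (1 + 2 * n))
    return float(r), float(min(p, 1.0))
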