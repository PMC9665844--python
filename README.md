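# frognav

Space-use and translocation-navigation analysis for tracked amphibians
(and other small, site-faithful animals), with a seeded movement simulator
for end-to-end validation.

Neotropical poison frogs defend small territories, shuttle tadpoles to
scattered rearing pools, and — when experimentally displaced — often walk
straight back home. Quantifying that behavior from field relocations
("fixes") raises a chain of methodological problems this package solves in
one place:

* **Sampling-rate standardization.** Field effort is uneven: interesting
  behaviors get oversampled, and every spatial metric inflates with fix
  density. A two-step downsampling rule thins unusually dense tracking
  days (protecting rare parental/mating fixes and temporal spread) and
  then enforces a 60-min minimum sampling interval while keeping
  intermediate points of long (>20 m), fast movements, yielding 3–7 fixes
  per animal-day (median 4).
* **Space use.** Per-day cumulative travel; movement extent as the 100%
  minimum convex polygon (MCP) and the maximum pairwise distance between
  fixes; and home range as the area inside the 95% contour of a kernel
  utilization distribution (UD), using a Gaussian product kernel with a
  per-axis two-stage direct plug-in bandwidth (the Sheather–Jones /
  Wand–Jones family).
* **Behavior-day classification.** Each tracking day is labeled
  `parental`, `mating`, or `other` from behavioral annotations plus 1-m
  proximity to breeding pools or opposite-sex encounters (parental
  overrides mating; *O. sylvatica* males are exempt from the
  pool-proximity rule).
* **Translocation navigation.** For an animal released `d` meters from
  home: homing success (covered ≥ 70% of `d` within 3 or 6 days for ~50 m
  or ~200 m translocations), explored area (union of 5-m perceptual
  buffers around the path), straightness (net displacement over path
  length of the homing trajectory, truncated at arrival), signed angular
  deviation from the home bearing at a distance band scaled to ~20% of
  `d`, and homing duration in daytime hours (12-h nights excluded).
* **Circular statistics.** The directed Rayleigh (V) test of homeward
  orientation, `V = r·cos(θ̄ − μ_home)` with `u = V·√(2n)` against the
  standard-normal upper tail (or a seeded Monte-Carlo p), and a two-group
  comparison of angular distributions via MANOVA on the (cos θ, sin θ)
  responses with the exact-F Wilks' Λ transform.
* **Simulation.** Residents follow a discrete Ornstein–Uhlenbeck walk
  around a home center (per-axis stationary sd `σ/√(κ(2−κ))`) with
  day-type-dependent step noise and pool round-trips on parental days,
  observed through the irregular diurnal sampling protocol. Translocated
  animals follow a biased correlated random walk switching between
  `local`, `explore`, and `home` states with von Mises headings. All
  ground truth is returned, so every estimator is tested against known
  parameters.

## Worked example

Simulate one resident for two weeks, standardize the sampling, summarize
its space use, then translocate it and score the homing attempt:

```python
import numpy as np
from frognav import (ResidentParams, simulate_resident,
                     downsample_two_step, summarize_space_use,
                     HomeArea, HomingParams, simulate_translocation,
                     summarize_navigation)

rng = np.random.default_rng(5)
traj, _ = simulate_resident(ResidentParams(), n_days=14, rng=rng,
                            animal_id="frog-01")
traj = downsample_two_step(traj)
summary = summarize_space_use(traj)

home = HomeArea(traj.fixes)
rec, _ = simulate_translocation(HomingParams(), home, rng,
                                animal_id="frog-01")
nav = summarize_navigation(rec)
```

which prints (via the obvious f-strings):

```text
days tracked:      14
mean daily travel: 18.3 m
movement extent:   348.2 m2 (MCP)
max linear extent: 28.0 m
95% UD home range: 368.6 m2
homing:            True
explored area:     474 m2
straightness:      0.97
angular deviation: -0.24 rad
homing duration:   3.4 h
```

The frog used a ~350 m² territory; after a 50-m displacement it oriented
within 0.24 rad of the true home bearing at the 10-m evaluation band,
returned along a nearly straight path (straightness 0.97, where 1 is a
perfect beeline), and crossed the 10-m home buffer 3.4 daytime hours
after release.

The same pipeline is scriptable from a shell:

```sh
frognav simulate  --seed 4 --out-dir study/input
frognav preprocess --in-dir study/input   --out-dir study/derived
frognav spaceuse   --in-dir study/derived --out-dir study/derived
frognav navigation --in-dir study/input   --out-dir study/derived
frognav circtest   --in-dir study/derived --out study/derived/circtest.json
```

emitting tidy CSV summaries (ready for LM/GLM/beta-regression modeling in
external tools), GeoJSON hulls and normalized trajectories, and a JSON
circular-statistics report.

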