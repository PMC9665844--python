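"""End-to-end pipeline stages over the standard CSV input set.

Each stage reads the tables the previous stage (or the simulator) wrote
and emits tidy summary tables ready for downstream statistical modeling;
model fitting itself is out of scope here.  All outputs are deterministic
given deterministic inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import circstats, io, navigation, preprocess, spaceuse
from .core import (DistanceClass, HomeArea, Sex, TranslocationRecord,
                   Trajectory)


def run_simulate(seed: int, out_dir, scenario: str = "paper-like",
                 n_per_group: int = 4, n_days: int = 12):
    from .simulate import make_study
    study = make_study(seed, n_per_group=n_per_group, n_days=n_days,
                       scenario=scenario)
    study.write(out_dir)
    return study


def run_preprocess(in_dir, out_dir,
                   cfg: Optional[preprocess.DownsampleConfig] = None
                   ) -> None:
    """Downsample the fix table and emit day records."""
    cfg = cfg or preprocess.DownsampleConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajs = io.read_fixes(in_dir / "fixes.csv")
    pools_path = in_dir / "pools.csv"
    pools = []
    if pools_path.exists():
        pdf = pd.read_csv(pools_path)
        pools = list(zip(pdf["x"], pdf["y"]))

    daily_mean = None
    counts = [len(v) for tr in trajs for v in tr.split_days().values()]
    if counts:
        daily_mean = sum(counts) / len(counts)

    downsampled = [preprocess.downsample_two_step(tr, cfg, daily_mean)
                   for tr in trajs]
    io.write_fixes(downsampled, out_dir / "fixes_downsampled.csv")

    rows = []
    for tr in downsampled:
        for rec in preprocess.label_behavior_days(tr, pools=pools):
            rows.append({
                "animal_id": rec.animal_id,
                "date": rec.date.isoformat(),
                "day_type": rec.day_type.value,
                "daily_travel_m": repr(rec.daily_travel_m),
                "n_fixes": rec.n_fixes,
            })
    pd.DataFrame(rows).to_csv(out_dir / "day_records.csv", index=False)


def run_spaceuse(in_dir, out_dir,
                 kde: Optional[spaceuse.KDEConfig] = None,
                 min_days_for_range: int = 7) -> None:
    """Space-use summaries and hull geometries from downsampled fixes."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajs = io.read_fixes(in_dir / "fixes_downsampled.csv")
    rows, hulls, props = [], [], []
    for tr in trajs:
        s = spaceuse.summarize_space_use(tr, kde, min_days_for_range)
        rows.append({
            "animal_id": s.animal_id,
            "species": s.species.value if s.species else "",
            "sex": s.sex.value if s.sex else "",
            "days_tracked": s.days_tracked,
            "daily_travel_mean_m": repr(s.daily_travel_mean_m),
            "extent_area_m2": "" if s.extent_area_m2 is None
            else repr(s.extent_area_m2),
            "extent_distance_m": "" if s.extent_distance_m is None
            else repr(s.extent_distance_m),
            "home_range_m2": "" if s.home_range_m2 is None
            else repr(s.home_range_m2),
        })
        hull, _, _ = spaceuse.movement_extent_mcp(tr.fixes)
        hulls.append(hull)
        props.append({"animal_id": tr.animal_id, "kind": "mcp"})
    pd.DataFrame(rows).to_csv(out_dir / "space_use.csv", index=False)
    io.write_geometries(hulls, out_dir / "hulls.geojson", props)


def load_translocations(in_dir) -> list[TranslocationRecord]:
    """Assemble translocation records from the standard CSV set.

    Home areas come from each animal's pre-translocation fixes in
    ``fixes.csv``; post-release tracks from ``nav_fixes.csv``.
    """
    in_dir = Path(in_dir)
    homes = {tr.animal_id: HomeArea(tr.fixes)
             for tr in io.read_fixes(in_dir / "fixes.csv")}
    tracks = {tr.animal_id: tr
              for tr in io.read_fixes(in_dir / "nav_fixes.csv")}
    tdf = pd.read_csv(in_dir / "translocations.csv")
    records = []
    for _, row in tdf.iterrows():
        aid = str(row["animal_id"])
        records.append(TranslocationRecord(
            animal_id=aid,
            release_point=(float(row["release_x"]),
                           float(row["release_y"])),
            release_time=pd.Timestamp(row["release_time"]).to_pydatetime(),
            distance_class=DistanceClass(row["distance_class"]),
            home=homes[aid],
            track=tracks[aid]))
    return records


def run_navigation(in_dir, out_dir,
                   cfg: Optional[navigation.NavConfig] = None) -> None:
    """Navigation summaries, normalized tracks, and the circular table."""
    cfg = cfg or navigation.NavConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = load_translocations(in_dir)

    rows, circ_rows, norm_trajs, props = [], [], [], []
    for rec in records:
        s = navigation.summarize_navigation(rec, cfg)
        rows.append({
            "animal_id": s.animal_id,
            "species": s.species.value if s.species else "",
            "sex": s.sex.value if s.sex else "",
            "distance_class": rec.distance_class.value,
            "homing": int(s.homing),
            "explored_area_m2": repr(s.explored_area_m2),
            "straightness": "" if s.straightness is None
            else repr(s.straightness),
            "angular_deviation_rad": "" if s.angular_deviation_rad is None
            else repr(s.angular_deviation_rad),
            "homing_duration_h": "" if s.homing_duration_h is None
            else repr(s.homing_duration_h),
        })
        if s.angular_deviation_rad is not None:
            circ_rows.append({
                "animal_id": s.animal_id,
                "species": s.species.value if s.species else "",
                "sex": s.sex.value if s.sex else "",
                "distance_class": rec.distance_class.value,
                "angle_rad": repr(s.angular_deviation_rad),
            })
        norm_trajs.append(navigation.normalize_homeward(rec))
        props.append({"animal_id": rec.animal_id,
                      "distance_class": rec.distance_class.value})
    pd.DataFrame(rows).to_csv(out_dir / "nav_summary.csv", index=False)
    pd.DataFrame(circ_rows).to_csv(out_dir / "circular.csv", index=False)
    io.write_geometries(norm_trajs, out_dir / "normalized_tracks.geojson",
                        props)


def run_circtest(in_dir, out_path, mc_seed: int = 0) -> dict:
    """Directed-orientation and sex-comparison tests per group.

    For each (species, distance class) cell: a V-test of homeward
    orientation per sex (home direction = 0 in the normalized frame) and,
    when both sexes have enough angles, the trigonometric MANOVA
    comparing the sexes.  Writes a JSON report and returns it.
    """
    df = pd.read_csv(Path(in_dir) / "circular.csv")
    report: dict = {}
    for (species, dclass), sub in df.groupby(["species", "distance_class"],
                                             sort=True):
        cell: dict = {}
        for sex in (Sex.FEMALE.value, Sex.MALE.value):
            angles = sub.loc[sub["sex"] == sex, "angle_rad"].astype(
                float).to_numpy()
            if len(angles) >= 5:
                v, p = circstats.rayleigh_homeward(angles, mu_home=0.0)
                cell[f"vtest_{sex}"] = {"V": v, "p": p, "n": len(angles)}
        a = sub.loc[sub["sex"] == "female", "angle_rad"].astype(
            float).to_numpy()
        b = sub.loc[sub["sex"] == "male", "angle_rad"].astype(
            float).to_numpy()
        if len(a) >= 3 and len(b) >= 3:
            try:
                f, dfs, p = circstats.trig_group_test(a, b)
                cell["sex_comparison"] = {"F": f, "df": list(dfs), "p": p}
            except ValueError:
                pass
        report[f"{species}_{dclass}"] = cell
    Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True)
                              + "\n")
    return report


def run_all(seed: int, work_dir, scenario: str = "paper-like",
            n_per_group: int = 4, n_days: int = 12) -> None:
    """simulate -> preprocess -> spaceuse -> navigation -> circtest."""
    work = Path(work_dir)
    run_simulate(seed, work / "input", scenario, n_per_group, n_days)
    run_preprocess(work / "input", work / "derived")
    run_spaceuse(work / "derived", work / "derived")
    run_navigation(work / "input", work / "derived")
    run_circtest(work / "derived", work / "derived" / "circtest.json")
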