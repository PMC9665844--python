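"""Readers and writers for fix tables and derived geometry.

Fix tables are delimited text (CSV/TSV) with configurable column names.
Geometry goes out as GeoJSON in the local planar frame (meters); the CRS
member declares an engineering frame so nothing downstream mistakes the
coordinates for longitude/latitude.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .core import (Behavior, Fix, FixSource, Sex, Species, Trajectory)

#: GeoJSON "crs" member used for all geometry output: a local engineering
#: frame in meters, not a geographic CRS.
LOCAL_FRAME_CRS = {"type": "name",
                   "properties": {"name": "urn:frognav:local-meters"}}


@dataclass
class ColumnSchema:
    """Mapping from logical field names to table column names."""

    id: str = "animal_id"
    time: str = "t"
    x: str = "x"
    y: str = "y"
    behavior: Optional[str] = "behavior"
    species: Optional[str] = "species"
    sex: Optional[str] = "sex"
    weight: Optional[str] = "weight_g"
    source: Optional[str] = "source"


def _parse_behavior(value, row_label) -> Behavior:
    if value is None or (isinstance(value, float) and pd.isna(value)) \
            or value == "":
        return Behavior.OTHER
    try:
        return Behavior(str(value))
    except ValueError:
        warnings.warn(f"unknown behavior label {value!r} at row {row_label}; "
                      f"recorded as 'unknown'")
        return Behavior.UNKNOWN


def read_fixes(
    path: Union[str, Path],
    schema: Optional[ColumnSchema] = None,
    sep: str = ",",
    on_duplicate: Literal["error", "keep_first"] = "error",
) -> list[Trajectory]:
    """Read a delimited fix table into per-animal trajectories.

    Fixes are grouped by animal and sorted by time regardless of row order.
    Duplicate (animal, time) rows raise by default; ``keep_first`` keeps the
    first row and drops the rest.  Unparseable timestamps or non-numeric
    coordinates raise an error naming the offending row.
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (schema.id, schema.time, schema.x, schema.y):
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing from {path}")

    try:
        times = pd.to_datetime(df[schema.time], format="mixed")
    except (ValueError, TypeError):
        # re-parse row by row to name the culprit
        for i, v in df[schema.time].items():
            try:
                pd.to_datetime(v)
            except (ValueError, TypeError):
                raise ValueError(
                    f"unparseable timestamp {v!r} at row {i}") from None
        raise
    coords = {}
    for col in (schema.x, schema.y):
        # python float() is correctly rounded, so repr-written tables
        # round-trip bit-exactly
        vals = []
        for i, v in df[col].items():
            try:
                vals.append(float(v))
            except (ValueError, TypeError):
                raise ValueError(
                    f"non-numeric coordinate {v!r} in column {col!r} "
                    f"at row {i}") from None
        coords[col] = pd.Series(vals, index=df.index)

    trajectories: list[Trajectory] = []
    for animal_id, sub in df.groupby(schema.id, sort=True):
        order = times[sub.index].sort_values(kind="stable").index
        seen: dict = {}
        fixes: list[Fix] = []
        for i in order:
            t = times[i].to_pydatetime()
            if t in seen:
                if on_duplicate == "error":
                    raise ValueError(
                        f"duplicate fix time {t} for animal {animal_id!r} "
                        f"(rows {seen[t]} and {i})")
                continue
            seen[t] = i
            behavior = (_parse_behavior(df[schema.behavior][i], i)
                        if schema.behavior in df.columns else Behavior.OTHER)
            source = FixSource.TRACKING
            if schema.source in df.columns and pd.notna(df[schema.source][i]):
                source = FixSource(df[schema.source][i])
            fixes.append(Fix(str(animal_id), t,
                             float(coords[schema.x][i]),
                             float(coords[schema.y][i]),
                             behavior, source))

        def _meta(col, cast):
            if col in df.columns:
                v = sub[col].dropna()
                if len(v):
                    return cast(v.iloc[0])
            return None

        trajectories.append(Trajectory(
            animal_id=str(animal_id),
            fixes=tuple(fixes),
            species=_meta(schema.species, Species),
            sex=_meta(schema.sex, Sex),
            weight_g=_meta(schema.weight, float),
        ))
    return trajectories


def write_fixes(trajectories: Sequence[Trajectory],
                path: Union[str, Path], sep: str = ",") -> None:
    """Write trajectories back to a delimited fix table."""
    rows = []
    for tr in trajectories:
        for f in tr.fixes:
            rows.append({
                "animal_id": f.animal_id,
                "t": f.t.isoformat(),
                "x": repr(f.x),
                "y": repr(f.y),
                "behavior": f.behavior.value,
                "source": f.source.value,
                "species": tr.species.value if tr.species else "",
                "sex": tr.sex.value if tr.sex else "",
                "weight_g": "" if tr.weight_g is None else repr(tr.weight_g),
            })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _feature(obj, properties=None) -> dict:
    if isinstance(obj, Trajectory):
        geom = {"type": "LineString" if len(obj) > 1 else "Point",
                "coordinates": ([[f.x, f.y] for f in obj.fixes]
                                if len(obj) > 1
                                else [obj.fixes[0].x, obj.fixes[0].y])}
        props = {"animal_id": obj.animal_id,
                 "times": [f.t.isoformat() for f in obj.fixes]}
    elif isinstance(obj, BaseGeometry):
        geom = mapping(obj)
        props = {}
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} to GeoJSON")
    props.update(properties or {})
    return {"type": "Feature", "geometry": json.loads(json.dumps(geom)),
            "properties": props}


def write_geometries(objs: Iterable, path: Union[str, Path],
                     properties: Optional[Sequence[dict]] = None) -> None:
    """Write polygons/lines/trajectories as a GeoJSON FeatureCollection.

    Coordinates are planar meters; writing then reading then writing again
    produces byte-identical files (floats serialized via repr round-trip).
    """
    objs = list(objs)
    if not objs:
        raise ValueError("no geometries to write")
    if properties is None:
        properties = [None] * len(objs)
    fc = {"type": "FeatureCollection", "crs": LOCAL_FRAME_CRS,
          "features": [_feature(o, p) for o, p in zip(objs, properties)]}
    Path(path).write_text(json.dumps(fc, indent=None, separators=(",", ":"))
                          + "\n")


def read_geometries(path: Union[str, Path]) -> list:
    """Read a GeoJSON FeatureCollection written by :func:`write_geometries`.

    Trajectory features (LineString/Point with ``times``) come back as
    :class:`Trajectory`; everything else as shapely geometry.
    """
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if "times" in props:
            times = [pd.Timestamp(s).to_pydatetime() for s in props["times"]]
            coords = feat["geometry"]["coordinates"]
            if feat["geometry"]["type"] == "Point":
                coords = [coords]
            fixes = tuple(Fix(props["animal_id"], t, x, y)
                          for t, (x, y) in zip(times, coords))
            out.append(Trajectory(props["animal_id"], fixes))
        else:
            out.append(shape(feat["geometry"]))
    return out


def read_temperature(path: Union[str, Path], sep: str = ",") -> pd.DataFrame:
    """Read a temperature log with columns ``t`` (timestamp), ``temp_C``."""
    df = pd.read_csv(path, sep=sep)
    df["t"] = pd.to_datetime(df["t"])
    df["temp_C"] = pd.to_numeric(df["temp_C"])
    return df.sort_values("t").reset_index(drop=True)
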