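"""File formats: keypoint CSV, arena YAML, region JSON, TIFF, metrics CSV.

The keypoint CSV is the de-facto pose-estimation dialect: three header
rows (scorer / bodyparts / coords) with x, y, likelihood columns per
bodypart and a leading frame-index column.  Images are written as 16-bit
TIFF.  Region annotations travel as polygon JSON with 0-based pixel
coordinates, ``[x, y]`` pairs, y-down.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import ArenaSpec, Trajectory
from .histology import RegionAnnotation

__all__ = [
    "write_keypoint_csv",
    "read_keypoint_csv",
    "arena_to_yaml",
    "arena_from_yaml",
    "write_tiff",
    "read_tiff",
    "region_to_json",
    "region_from_json",
]

BODYPARTS = ("nose", "head", "body")


def write_keypoint_csv(traj: Trajectory, path: str | Path, scorer: str = "pbmstudy") -> None:
    """Write a trajectory in the three-header-row keypoint CSV dialect."""
    cols = pd.MultiIndex.from_product(
        [[scorer], BODYPARTS, ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    n = len(traj)
    data = np.empty((n, 9))
    for k, xy in enumerate((traj.nose_xy, traj.head_xy, traj.body_xy)):
        data[:, 3 * k] = xy[:, 0]
        data[:, 3 * k + 1] = xy[:, 1]
        data[:, 3 * k + 2] = traj.likelihood[:, k]
    pd.DataFrame(data, columns=cols).to_csv(path, index=True, index_label=None)


def read_keypoint_csv(path: str | Path, frame_rate_hz: float) -> Trajectory:
    """Read the keypoint CSV dialect; timestamps come from the frame index
    divided by ``frame_rate_hz`` (the dialect itself stores no times)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    get = lambda part, coord: df[(scorer, part, coord)].to_numpy(dtype=float)
    xy = {p: np.column_stack([get(p, "x"), get(p, "y")]) for p in BODYPARTS}
    lik = np.column_stack([get(p, "likelihood") for p in BODYPARTS])
    time_s = df.index.to_numpy(dtype=float) / frame_rate_hz
    return Trajectory(time_s, xy["nose"], xy["head"], xy["body"], lik)


def arena_to_yaml(arena: ArenaSpec, path: str | Path) -> None:
    d = dataclasses.asdict(arena)
    d = {k: _plain(v) for k, v in d.items() if v is not None}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def arena_from_yaml(path: str | Path) -> ArenaSpec:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("arm_labels", "arm_angles_deg", "platform_center"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "object_centers" in d and d["object_centers"] is not None:
        d["object_centers"] = {k: tuple(v) for k, v in d["object_centers"].items()}
    return ArenaSpec(**d)


def _plain(v):
    if isinstance(v, tuple):
        return [_plain(x) for x in v]
    if isinstance(v, dict):
        return {k: _plain(x) for k, x in v.items()}
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Save an intensity image as 16-bit TIFF (values clipped to uint16)."""
    arr = np.clip(np.asarray(image), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), np.round(arr).astype(np.uint16))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def region_to_json(region: RegionAnnotation, path: str | Path) -> None:
    """Polygon JSON: [x, y] pixel pairs, 0-based, y-down (x = column)."""
    d = {
        "region_label": region.region_label,
        "pixel_size_um": region.pixel_size_um,
        "include_polygons": [
            [[float(c), float(r)] for r, c in np.asarray(p)] for p in region.include_polygons
        ],
        "exclude_polygons": [
            [[float(c), float(r)] for r, c in np.asarray(p)] for p in region.exclude_polygons
        ],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def region_from_json(path: str | Path) -> RegionAnnotation:
    d = json.loads(Path(path).read_text())
    to_rc = lambda polys: [np.array([[y, x] for x, y in p]) for p in polys]
    return RegionAnnotation(
        region_label=d["region_label"],
        include_polygons=to_rc(d.get("include_polygons", [])),
        exclude_polygons=to_rc(d.get("exclude_polygons", [])),
        pixel_size_um=d.get("pixel_size_um", 0.6),
    )
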