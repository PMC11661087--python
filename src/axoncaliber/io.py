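"""File formats and run provenance.

Images travel as single-channel multi-frame TIFF; geometry and results as
JSON; measurements and summaries as CSV.  Units are micrometers in every
interface — pixel coordinates never cross a module boundary.  Every
output carries the seed and a short hash of the configuration that
produced it, so reruns can be verified byte-for-byte.

Measurement CSV schema (one header comment line with provenance):
    frame_time_min, segment_id, arc_pos_um, caliber_um,
    flag_below_resolution, flag_single_peak, flag_ambiguous
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .linescan import (
    BranchPointAnnotation,
    CaliberMeasurement,
    CenterlineAnnotation,
)
from .synthetic import AxonGroundTruth, SceneConfig

__all__ = [
    "config_hash",
    "write_image_stack",
    "read_image_stack",
    "write_ground_truth",
    "read_ground_truth",
    "write_centerline",
    "read_centerline",
    "read_swc",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_json_report",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = [
    "frame_time_min",
    "segment_id",
    "arc_pos_um",
    "caliber_um",
    "flag_below_resolution",
    "flag_single_peak",
    "flag_ambiguous",
]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration object or mapping."""
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_image_stack(path, frames) -> None:
    arr = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    tifffile.imwrite(path, arr, photometric="minisblack")


def read_image_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def write_ground_truth(path, truths: list[AxonGroundTruth], config: SceneConfig, extras: dict | None = None) -> None:
    """Ground-truth sidecar: per-frame geometry plus config echo and seed."""
    doc = {
        "config": _to_jsonable(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "frames": [
            {
                "frame_time": t.frame_time,
                "segments": {str(k): v.tolist() for k, v in t.segments.items()},
                "radius_profiles": {
                    str(k): {"s": s.tolist(), "r": r.tolist()}
                    for k, (s, r) in t.radius_profiles.items()
                },
                "branch_points": [
                    {
                        "location": list(map(float, bp.location)),
                        "parent_id": bp.parent_id,
                        "child_ids": list(bp.child_ids),
                    }
                    for bp in t.branch_points
                ],
            }
            for t in truths
        ],
    }
    if extras:
        doc.update(_to_jsonable(extras))
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def read_ground_truth(path) -> tuple[list[AxonGroundTruth], dict]:
    from .synthetic import BranchPoint

    doc = json.loads(Path(path).read_text())
    truths = []
    for fr in doc["frames"]:
        truths.append(
            AxonGroundTruth(
                segments={int(k): np.asarray(v) for k, v in fr["segments"].items()},
                radius_profiles={
                    int(k): (np.asarray(v["s"]), np.asarray(v["r"]))
                    for k, v in fr["radius_profiles"].items()
                },
                branch_points=[
                    BranchPoint(
                        location=tuple(bp["location"]),
                        parent_id=bp["parent_id"],
                        child_ids=tuple(bp["child_ids"]),
                    )
                    for bp in fr["branch_points"]
                ],
                frame_time=fr["frame_time"],
            )
        )
    return truths, doc


def write_centerline(path, centerline: CenterlineAnnotation) -> None:
    doc = {
        "segments": [
            {
                "id": sid,
                "points": pts.tolist(),
                "parent": centerline.parents.get(sid),
            }
            for sid, pts in sorted(centerline.segments.items())
        ],
        "branch_points": [
            {
                "location": list(map(float, bp.location)),
                "parent": bp.parent_id,
                "children": list(bp.child_ids),
            }
            for bp in centerline.branch_points
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))


def read_centerline(path) -> CenterlineAnnotation:
    """Read the documented centerline JSON schema (points in um)."""
    doc = json.loads(Path(path).read_text())
    segments = {int(s["id"]): np.asarray(s["points"], dtype=float) for s in doc["segments"]}
    parents = {int(s["id"]): s.get("parent") for s in doc["segments"]}
    bps = [
        BranchPointAnnotation(
            location=tuple(bp["location"]),
            parent_id=bp.get("parent"),
            child_ids=tuple(bp.get("children", ())),
        )
        for bp in doc.get("branch_points", [])
    ]
    return CenterlineAnnotation(segments=segments, branch_points=bps, parents=parents)


def read_swc(path, scale: float = 1.0) -> CenterlineAnnotation:
    """Import an SWC morphology as a 2D centerline annotation.

    The x, y columns (times ``scale``, for unit conversion) become the
    planar centerline; z and the SWC radius field are ignored.  Each
    unbranched run of nodes becomes one segment; nodes with more than one
    child become branch points.
    """
    nodes: dict[int, tuple[float, float, int]] = {}
    children: dict[int, list[int]] = {}
    order: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        nid, _t, x, y, _z, _r, parent = parts[:7]
        nid, parent = int(nid), int(parent)
        nodes[nid] = (float(x) * scale, float(y) * scale, parent)
        children.setdefault(parent, []).append(nid)
        order.append(nid)
    roots = [n for n in order if nodes[n][2] == -1]
    if not roots:
        raise ValueError("SWC has no root node")
    segments: dict[int, np.ndarray] = {}
    parents: dict[int, int | None] = {}
    bps: list[BranchPointAnnotation] = []
    next_id = 0

    def build(first: int, parent_seg: int | None, branch_loc) -> int:
        # one unbranched run of nodes; child segments start at their branch point
        nonlocal next_id
        sid = next_id
        next_id += 1
        pts = ([] if branch_loc is None else [branch_loc]) + [nodes[first][:2]]
        cur = first
        while len(children.get(cur, [])) == 1:
            cur = children[cur][0]
            pts.append(nodes[cur][:2])
        segments[sid] = np.asarray(pts, dtype=float)
        parents[sid] = parent_seg
        kids = children.get(cur, [])
        if len(kids) > 1:
            loc = nodes[cur][:2]
            child_ids = tuple(build(k, sid, loc) for k in kids)
            bps.append(BranchPointAnnotation(location=loc, parent_id=sid, child_ids=child_ids))
        return sid

    for root in roots:
        build(root, None, None)
    return CenterlineAnnotation(segments=segments, branch_points=bps, parents=parents)


def measurements_to_frame(measurements: list[CaliberMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "frame_time_min": m.frame_time,
            "segment_id": m.segment_id,
            "arc_pos_um": m.arc_pos,
            "caliber_um": m.caliber if m.caliber is not None else np.nan,
            "flag_below_resolution": int(m.below_resolution),
            "flag_single_peak": int(m.single_peak),
            "flag_ambiguous": int(m.ambiguous_peaks),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements_csv(path, measurements: list[CaliberMeasurement], config=None, seed=None) -> None:
    df = measurements_to_frame(measurements)
    header = f"# config_hash={config_hash(config) if config is not None else 'none'} seed={seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_measurements_csv(path) -> list[CaliberMeasurement]:
    df = pd.read_csv(path, comment="#")
    out = []
    for _, row in df.iterrows():
        cal = row["caliber_um"]
        out.append(
            CaliberMeasurement(
                segment_id=int(row["segment_id"]),
                arc_pos=float(row["arc_pos_um"]),
                caliber=None if pd.isna(cal) else float(cal),
                below_resolution=bool(row["flag_below_resolution"]),
                single_peak=bool(row["flag_single_peak"]),
                ambiguous_peaks=bool(row["flag_ambiguous"]),
                frame_time=float(row["frame_time_min"]),
            )
        )
    return out


def write_json_report(path, payload: dict, config=None, seed=None) -> None:
    doc = dict(_to_jsonable(payload))
    doc["provenance"] = {
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))
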