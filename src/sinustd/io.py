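"""CSV/JSON serialisation of outlines and profiles.

Outline CSV columns: ``id, vertex_index, x_mm, y_mm`` (one row per vertex,
in arc order). A JSON sidecar (same path + ``.json``) carries the baseline
termini, the origin and the calibration:

    {"outline_id": ..., "scale_mm_per_px": ...,
     "baseline": {"left": [x, y], "right": [x, y]}, "origin": [x, y]}

Profile CSV columns: ``outline_id, baseline_length_mm, angle_deg,
line_length_mm, standardized_length, intersection_x_mm, intersection_y_mm,
n_crossings`` — self-contained, so profiles can be compared without their
source outline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .geometry import BaselineSpec, OriginSpec, Point2D, SinusOutline, SinusProfile

OUTLINE_COLUMNS = ["id", "vertex_index", "x_mm", "y_mm"]
PROFILE_COLUMNS = ["outline_id", "baseline_length_mm", "angle_deg", "line_length_mm",
                   "standardized_length", "intersection_x_mm", "intersection_y_mm",
                   "n_crossings"]


def save_outline(path, outline: SinusOutline, baseline: BaselineSpec,
                 origin: OriginSpec) -> None:
    path = Path(path)
    arr = outline.as_array()
    pd.DataFrame({
        "id": outline.id,
        "vertex_index": np.arange(len(arr)),
        "x_mm": arr[:, 0],
        "y_mm": arr[:, 1],
    }).to_csv(path, index=False)
    sidecar = {
        "outline_id": outline.id,
        "scale_mm_per_px": outline.scale_mm_per_px,
        "baseline": {
            "left": [baseline.left_terminus.x, baseline.left_terminus.y],
            "right": [baseline.right_terminus.x, baseline.right_terminus.y],
        },
        "origin": [origin.origin.x, origin.origin.y],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_outline(path) -> tuple[SinusOutline, BaselineSpec, OriginSpec]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read outline CSV {path}: {exc}") from exc
    missing = set(OUTLINE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"outline CSV {path} is missing columns {sorted(missing)}")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing outline sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    df = df.sort_values("vertex_index")
    outline = SinusOutline.from_coords(
        df[["x_mm", "y_mm"]].to_numpy(),
        id=str(meta.get("outline_id", df["id"].iloc[0])),
        scale_mm_per_px=float(meta.get("scale_mm_per_px", 1.0)))
    bl = meta["baseline"]
    baseline = BaselineSpec(Point2D(*map(float, bl["left"])), Point2D(*map(float, bl["right"])))
    origin = OriginSpec.from_origin(Point2D(*map(float, meta["origin"])), baseline)
    return outline, baseline, origin


def save_profile(path, profile: SinusProfile) -> None:
    B = profile.baseline.length_B
    rows = []
    for m in profile.measurements:
        rows.append({
            "outline_id": profile.outline_id,
            "baseline_length_mm": B,
            "angle_deg": m.angle_theta,
            "line_length_mm": m.line_length_L,
            "standardized_length": m.line_length_L / B,
            "intersection_x_mm": m.intersection.x,
            "intersection_y_mm": m.intersection.y,
            "n_crossings": m.n_crossings,
        })
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def load_profile_vectors(path) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """Read a profile CSV into (outline_id, angles, raw lengths, standardized lengths)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read profile CSV {path}: {exc}") from exc
    missing = {"outline_id", "angle_deg", "line_length_mm", "standardized_length"} - set(df.columns)
    if missing:
        raise FormatError(f"profile CSV {path} is missing columns {sorted(missing)}")
    df = df.sort_values("angle_deg")
    return (str(df["outline_id"].iloc[0]),
            df["angle_deg"].to_numpy(float),
            df["line_length_mm"].to_numpy(float),
            df["standardized_length"].to_numpy(float))
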