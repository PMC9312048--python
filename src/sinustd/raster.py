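"""Raster and ImageJ interoperability.

This module is the only place where the raster y-down pixel convention is
converted to the package's y-up millimetre geometry frame. It provides

* orbital-breadth scale calibration (``calibrate_scale``),
* binary-mask outer-contour extraction with area/perimeter (``extract_outer_contour``),
* rasterisation of a vector outline back to a mask (``rasterize_outline``),
* a reader/writer for ImageJ ``.roi`` files and ``RoiSet.zip`` archives
  (big-endian, magic ``Iout``; polygon, freehand and line types), and
* the 59-ray measurement-aid overlay (``render_overlay``).

Area follows the foreground pixel count; the perimeter is the length of the
traced sub-pixel boundary polygon of the (hole-filled) foreground, i.e. the
outer contour only — internal septa and holes are ignored, matching how the
outline is traced.
"""

from __future__ import annotations

import io
import math
import struct
import zipfile
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage
from skimage import measure as sk_measure

from .errors import FormatError
from .geometry import BaselineSpec, Point2D, SinusOutline, ray_angles

HOWELLS_ORBITAL_BREADTH_MM = 39.49  # Howells' pooled orbital-breadth mean

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class CalibratedImage:
    """A pixel grid with its millimetre-per-pixel calibration."""

    pixels: np.ndarray
    mm_per_px: float

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0.0:
            raise FormatError("mm_per_px must be > 0")


@dataclass(frozen=True)
class RegionStats:
    """Sinus size summaries used as a scaling back-check."""

    area: float
    perimeter: float


def calibrate_scale(p_dacryon: Sequence[float], p_ectoconchion: Sequence[float],
                    target_mm: float = HOWELLS_ORBITAL_BREADTH_MM) -> float:
    """Millimetres per pixel from an orbital-breadth landmark pair.

    The pixel distance dacryon-to-ectoconchion is mapped onto ``target_mm``
    (default: the 39.49 mm Howells average), so the landmark segment measures
    exactly ``target_mm`` after calibration.
    """
    dx = float(p_ectoconchion[0]) - float(p_dacryon[0])
    dy = float(p_ectoconchion[1]) - float(p_dacryon[1])
    dist_px = math.hypot(dx, dy)
    if dist_px == 0.0:
        raise FormatError("calibration landmarks coincide")
    if target_mm <= 0.0:
        raise FormatError("target_mm must be > 0")
    return target_mm / dist_px


def _clip_arc_above(points: np.ndarray, y0: float, tol: float) -> list[np.ndarray]:
    """Maximal sub-polylines of a closed contour lying on/above the line y = y0.

    Crossing points are interpolated exactly onto y0; runs are returned in
    traversal order.
    """
    runs: list[list[np.ndarray]] = []
    cur: list[np.ndarray] = []

    def flush() -> None:
        if len(cur) >= 2:
            runs.append(list(cur))
        cur.clear()

    n = len(points)
    for i in range(n - 1):
        p, q = points[i], points[i + 1]
        p_in, q_in = p[1] >= y0 - tol, q[1] >= y0 - tol
        if p_in:
            if not cur:
                cur.append(p)
            if q_in:
                cur.append(q)
            else:
                t = (y0 - p[1]) / (q[1] - p[1])
                cur.append(np.array([p[0] + t * (q[0] - p[0]), y0]))
                flush()
        elif q_in:
            t = (y0 - p[1]) / (q[1] - p[1])
            cur.append(np.array([p[0] + t * (q[0] - p[0]), y0]))
            cur.append(q)
    flush()
    return [np.array(r) for r in runs]


def extract_outer_contour(mask: CalibratedImage, baseline_row: float,
                          outline_id: str = "mask"
                          ) -> tuple[SinusOutline, BaselineSpec, RegionStats]:
    """Trace the outer contour of a single-component binary mask.

    ``baseline_row`` is the pixel row (y-down) of the supraorbital baseline.
    The foreground must be one 8-connected component reaching that row. Holes
    are filled before tracing so only the outer contour is followed; the
    above-baseline portion of it becomes the sinus arc, anchored at its two
    baseline crossings (which define the returned :class:`BaselineSpec`).

    Area is the foreground pixel count scaled to mm^2; the perimeter is the
    length of the full traced boundary polygon in mm.
    """
    fg = np.asarray(mask.pixels) > 0
    if not fg.any():
        raise FormatError("empty mask: no foreground pixels")
    _, n_comp = ndimage.label(fg, structure=_EIGHT_CONNECTED)
    if n_comp > 1:
        raise FormatError(
            f"mask has {n_comp} connected components; discontinuous lobes are not eligible")
    filled = ndimage.binary_fill_holes(fg)

    contours = sk_measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise FormatError("could not trace a boundary contour")
    contour = max(contours, key=len)  # (row, col) vertices, closed loop

    s = mask.mm_per_px
    h = fg.shape[0]
    pts_mm = np.column_stack([contour[:, 1] * s, (h - 1 - contour[:, 0]) * s])
    if not np.allclose(pts_mm[0], pts_mm[-1]):
        pts_mm = np.vstack([pts_mm, pts_mm[0]])

    perimeter = float(np.linalg.norm(np.diff(pts_mm, axis=0), axis=1).sum())
    area = float(np.count_nonzero(fg)) * s * s

    y0 = (h - 1 - float(baseline_row)) * s
    # start the closed loop at its lowest vertex so no above-baseline run is
    # split across the array seam
    start = int(np.argmin(pts_mm[:, 1]))
    ring = np.vstack([pts_mm[start:-1], pts_mm[:start], pts_mm[start:start + 1]])
    runs = _clip_arc_above(ring, y0, tol=0.25 * s)

    def run_length(r: np.ndarray) -> float:
        return float(np.linalg.norm(np.diff(r, axis=0), axis=1).sum())

    runs = [r for r in runs if run_length(r) > 0.0]
    if not runs:
        raise FormatError("foreground does not rise above the baseline row")
    arc = max(runs, key=run_length)
    # anchor the endpoints exactly on the baseline and orient left -> right
    arc = arc.copy()
    arc[0, 1] = y0
    arc[-1, 1] = y0
    if arc[0, 0] > arc[-1, 0]:
        arc = arc[::-1]
    keep = np.concatenate([[True], np.linalg.norm(np.diff(arc, axis=0), axis=1) > 1e-12])
    arc = arc[keep]
    if len(arc) < 3:
        raise FormatError("above-baseline arc is degenerate")

    baseline = BaselineSpec(Point2D(float(arc[0, 0]), y0), Point2D(float(arc[-1, 0]), y0))
    outline = SinusOutline.from_coords(arc, id=outline_id, scale_mm_per_px=s)
    return outline, baseline, RegionStats(area=area, perimeter=perimeter)


def rasterize_outline(outline: SinusOutline, baseline: BaselineSpec, mm_per_px: float,
                      margin_px: int = 10) -> tuple[CalibratedImage, int]:
    """Fill the region bounded by the arc and the baseline chord into a binary mask.

    Requires a level baseline (rotate first if tilted). Returns the mask and
    the pixel row of the baseline, ready for :func:`extract_outer_contour`.
    """
    from skimage.draw import polygon as sk_polygon

    if abs(baseline.left_terminus.y - baseline.right_terminus.y) > 1e-6:
        raise FormatError("rasterize_outline requires a level baseline; rotate_to_level first")
    arr = outline.as_array()
    s = mm_per_px
    minx = min(arr[:, 0].min(), baseline.left_terminus.x)
    maxx = max(arr[:, 0].max(), baseline.right_terminus.x)
    y_base = baseline.left_terminus.y
    maxy = arr[:, 1].max()

    width = int(math.ceil((maxx - minx) / s)) + 2 * margin_px + 1
    height = int(math.ceil((maxy - y_base) / s)) + 2 * margin_px + 1
    baseline_row = height - 1 - margin_px

    cols = margin_px + (arr[:, 0] - minx) / s
    rows = baseline_row - (arr[:, 1] - y_base) / s
    rr, cc = sk_polygon(rows, cols, shape=(height, width))
    img = np.zeros((height, width), dtype=np.uint8)
    img[rr, cc] = 1
    return CalibratedImage(pixels=img, mm_per_px=s), baseline_row


# ---------------------------------------------------------------------------
# ImageJ ROI files
# ---------------------------------------------------------------------------

ROI_MAGIC = b"Iout"
ROI_VERSION = 227
_ROI_TYPE_BYTES = {"polygon": 0, "line": 3, "freehand": 7}
_ROI_TYPE_NAMES = {v: k for k, v in _ROI_TYPE_BYTES.items()}
_HEADER_SIZE = 64


def write_roi(vertices: Sequence[Sequence[float]], roi_type: str = "polygon") -> bytes:
    """Encode vertices as an ImageJ ``.roi`` blob (big-endian, magic ``Iout``).

    Polygon and freehand ROIs store integer pixel coordinates relative to the
    bounding box; a line ROI stores its two endpoints as floats.
    """
    if roi_type not in _ROI_TYPE_BYTES:
        raise FormatError(f"unsupported ROI type {roi_type!r}")
    pts = [(int(round(x)), int(round(y))) for x, y in vertices]
    if roi_type == "line":
        if len(pts) != 2:
            raise FormatError("a line ROI needs exactly 2 points")
    elif len(pts) < 3:
        raise FormatError(f"a {roi_type} ROI needs at least 3 points")

    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = ROI_MAGIC
    struct.pack_into(">h", header, 4, ROI_VERSION)
    header[6] = _ROI_TYPE_BYTES[roi_type]
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    if roi_type == "line":
        struct.pack_into(">4f", header, 18, float(xs[0]), float(ys[0]),
                         float(xs[1]), float(ys[1]))
        return bytes(header)
    struct.pack_into(">h", header, 16, len(pts))
    body = struct.pack(f">{len(pts)}h", *[x - left for x in xs])
    body += struct.pack(f">{len(pts)}h", *[y - top for y in ys])
    return bytes(header) + body


def read_roi(data: bytes) -> dict:
    """Decode an ImageJ ``.roi`` blob into ``{"type": ..., "vertices": [(x, y), ...]}``."""
    if len(data) < _HEADER_SIZE:
        raise FormatError(f"truncated ROI file ({len(data)} bytes)")
    if data[0:4] != ROI_MAGIC:
        raise FormatError(f"bad ROI magic {data[0:4]!r}; expected {ROI_MAGIC!r}")
    type_byte = data[6]
    if type_byte not in _ROI_TYPE_NAMES:
        raise FormatError(f"unsupported ROI type byte {type_byte}")
    roi_type = _ROI_TYPE_NAMES[type_byte]
    top, left, _bottom, _right = struct.unpack_from(">4h", data, 8)
    if roi_type == "line":
        x1, y1, x2, y2 = struct.unpack_from(">4f", data, 18)
        return {"type": roi_type, "vertices": [(x1, y1), (x2, y2)]}
    (n,) = struct.unpack_from(">h", data, 16)
    need = _HEADER_SIZE + 4 * n
    if len(data) < need:
        raise FormatError(f"ROI file too short for {n} coordinates")
    xs = struct.unpack_from(f">{n}h", data, _HEADER_SIZE)
    ys = struct.unpack_from(f">{n}h", data, _HEADER_SIZE + 2 * n)
    return {"type": roi_type,
            "vertices": [(x + left, y + top) for x, y in zip(xs, ys)]}


def write_roi_file(path, vertices: Sequence[Sequence[float]],
                   roi_type: str = "polygon") -> None:
    with open(path, "wb") as fh:
        fh.write(write_roi(vertices, roi_type))


def read_roi_file(path) -> dict:
    with open(path, "rb") as fh:
        return read_roi(fh.read())


def write_roi_zip(path, rois: dict) -> None:
    """Write ``{name: (vertices, roi_type)}`` as an ImageJ RoiSet archive."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, (vertices, roi_type) in rois.items():
            entry = name if name.endswith(".roi") else name + ".roi"
            zf.writestr(entry, write_roi(vertices, roi_type))


def read_roi_zip(path) -> dict:
    """Read a RoiSet archive into ``{name: decoded_roi}``."""
    out = {}
    with zipfile.ZipFile(path) as zf:
        for entry in zf.namelist():
            if entry.endswith(".roi"):
                out[entry[:-4]] = read_roi(zf.read(entry))
    return out


# ---------------------------------------------------------------------------
# measurement-aid overlay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Overlay:
    """The ray-fan measurement aid: a horizontal baseline, a marked origin, one ray per angle.

    Segments are in raster pixel coordinates (y-down). ``to_raster`` draws a
    grayscale PNG-ready array; ``to_svg`` emits the same geometry as vectors.
    """

    segments: tuple          # ((x1, y1), (x2, y2)) per ray, pixel coords
    baseline: tuple          # ((x1, y1), (x2, y2))
    origin: tuple            # (x, y)
    size: tuple              # (width, height)

    def to_raster(self) -> np.ndarray:
        img = Image.new("L", self.size, color=0)
        draw = ImageDraw.Draw(img)
        draw.line([self.baseline[0], self.baseline[1]], fill=255, width=2)
        for (p, q) in self.segments:
            draw.line([p, q], fill=200, width=1)
        ox, oy = self.origin
        draw.ellipse([ox - 3, oy - 3, ox + 3, oy + 3], fill=255)
        return np.asarray(img)

    def to_svg(self) -> str:
        w, h = self.size
        lines = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}">']
        (bx1, by1), (bx2, by2) = self.baseline
        lines.append(f'<line x1="{bx1:.2f}" y1="{by1:.2f}" x2="{bx2:.2f}" y2="{by2:.2f}" '
                     'stroke="black" stroke-width="2"/>')
        for (p, q) in self.segments:
            lines.append(f'<line x1="{p[0]:.2f}" y1="{p[1]:.2f}" x2="{q[0]:.2f}" y2="{q[1]:.2f}" '
                         'stroke="gray" stroke-width="1"/>')
        ox, oy = self.origin
        lines.append(f'<circle cx="{ox:.2f}" cy="{oy:.2f}" r="3" fill="black"/>')
        lines.append("</svg>")
        return "\n".join(lines)


def render_overlay(angles: Sequence[float] | None = None,
                   baseline_length_px: int = 1000,
                   origin_marker_px: float | None = None,
                   ray_length_px: float | None = None,
                   margin_px: int = 20) -> Overlay:
    """Build the 59-ray measurement aid overlaid on a level baseline.

    One ray per angle emanates from the origin marker on the horizontal
    baseline; the default fan is the 59 angles from 3 to 177 degrees, so no
    ray lies on the baseline itself.
    """
    if angles is None:
        angles = ray_angles()
    if origin_marker_px is None:
        origin_marker_px = baseline_length_px / 2.0
    if ray_length_px is None:
        ray_length_px = 0.75 * baseline_length_px
    height = int(math.ceil(ray_length_px)) + 2 * margin_px
    width = baseline_length_px + 2 * margin_px
    base_y = height - margin_px
    ox = margin_px + float(origin_marker_px)
    segments = []
    for theta in angles:
        th = math.radians(theta)
        # geometry is y-up; raster rows grow downward
        ex = ox + ray_length_px * math.cos(th)
        ey = base_y - ray_length_px * math.sin(th)
        segments.append(((ox, base_y), (ex, ey)))
    return Overlay(segments=tuple(segments),
                   baseline=((margin_px, base_y), (margin_px + baseline_length_px, base_y)),
                   origin=(ox, base_y),
                   size=(width, height))
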