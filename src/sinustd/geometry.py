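"""Core geometry of the Total Difference Method ray fan.

The frontal sinus outline is modelled as an open polyline arc in a calibrated
millimetre frame (x toward the image-right baseline terminus, y superior).
The arc runs from the left baseline terminus to the right one; the
supraorbital baseline segment implicitly closes the region. All 59 profile
lines are cast from an origin on the baseline, at 3-degree steps measured
counterclockwise from the origin-to-right-terminus direction, and the line
length at each angle is the distance to the *outermost* crossing of the ray
with the arc.

Tolerances: crossings closer than ``MERGE_TOL`` (1e-9 mm) along a ray are
merged (this absorbs vertex-exact hits, which two adjacent segments both
report); arc endpoints must sit on the baseline termini within
``ANCHOR_TOL`` (1e-6 mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, EligibilityError, GeometryError

MERGE_TOL = 1e-9
ANCHOR_TOL = 1e-6

DEFAULT_START_DEG = 3.0
DEFAULT_STEP_DEG = 3.0
DEFAULT_END_DEG = 177.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Point2D:
    """A point in the calibrated millimetre frame (x right, y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class BaselineSpec:
    """The supraorbital baseline: its two termini and the derived total length B."""

    left_terminus: Point2D
    right_terminus: Point2D

    def __post_init__(self) -> None:
        if self.length_B <= 0.0:
            raise GeometryError("baseline termini coincide; baseline length must be > 0")

    @property
    def length_B(self) -> float:
        return self.left_terminus.distance(self.right_terminus)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from the left to the right terminus (the 0-degree datum)."""
        d = self.right_terminus.as_array() - self.left_terminus.as_array()
        return d / np.linalg.norm(d)

    @property
    def tilt_deg(self) -> float:
        """Signed angle of the baseline above the +x axis, in degrees."""
        d = self.direction
        return math.degrees(math.atan2(d[1], d[0]))


@dataclass(frozen=True)
class OriginSpec:
    """The ray origin on the baseline, with the right-baseline length RB and midline ratio r = RB / B."""

    origin: Point2D
    right_baseline_RB: float
    midline_ratio_r: float

    @classmethod
    def from_origin(cls, origin: Point2D, baseline: BaselineSpec,
                    tol: float = ANCHOR_TOL) -> "OriginSpec":
        """Build the spec for an origin point, verifying it lies on the baseline segment."""
        a = baseline.left_terminus.as_array()
        b = baseline.right_terminus.as_array()
        p = origin.as_array()
        ab = b - a
        t = float(np.dot(p - a, ab) / np.dot(ab, ab))
        if t < -tol or t > 1.0 + tol:
            raise GeometryError("origin lies outside the baseline segment")
        foot = a + np.clip(t, 0.0, 1.0) * ab
        if float(np.linalg.norm(p - foot)) > tol:
            raise GeometryError(
                f"origin is {np.linalg.norm(p - foot):.3g} mm off the baseline (tolerance {tol} mm)")
        rb = origin.distance(baseline.right_terminus)
        return cls(origin=origin, right_baseline_RB=rb,
                   midline_ratio_r=rb / baseline.length_B)


@dataclass(frozen=True)
class SinusOutline:
    """The traced sinus arc: an ordered open polyline from the left to the right baseline terminus.

    Vertices are stored in calibrated millimetres; ``scale_mm_per_px`` records
    the calibration a raster source was converted with (1.0 for native-mm data).
    """

    vertices: tuple
    id: str = "outline"
    scale_mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise GeometryError("outline needs at least 3 vertices")
        arr = self.as_array()
        steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise GeometryError("outline has coincident consecutive vertices")

    @classmethod
    def from_coords(cls, coords: Iterable[Sequence[float]], id: str = "outline",
                    scale_mm_per_px: float = 1.0) -> "SinusOutline":
        pts = tuple(Point2D(float(x), float(y)) for x, y in coords)
        return cls(vertices=pts, id=id, scale_mm_per_px=scale_mm_per_px)

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.vertices], dtype=float)


@dataclass(frozen=True)
class RayMeasurement:
    """One profile line: nominal angle, outermost intersection, length, crossing count."""

    angle_theta: float
    intersection: Point2D
    line_length_L: float
    n_crossings: int
    outermost_used: bool


@dataclass(frozen=True)
class SinusProfile:
    """The full ray-fan profile of one outline (59 measurements by default)."""

    outline_id: str
    baseline: BaselineSpec
    origin: OriginSpec
    measurements: tuple
    area: float | None = None
    perimeter: float | None = None

    @property
    def angles(self) -> np.ndarray:
        return np.array([m.angle_theta for m in self.measurements], dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([m.line_length_L for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class EligibilityReport:
    """Flags from the eligibility rules; the outline is usable iff all are true."""

    above_baseline: bool
    origin_interior: bool
    arc_continuous: bool
    messages: tuple = field(default=())

    @property
    def eligible(self) -> bool:
        return self.above_baseline and self.origin_interior and self.arc_continuous

    def __bool__(self) -> bool:
        return self.eligible


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ray_angles(start_deg: float = DEFAULT_START_DEG, step_deg: float = DEFAULT_STEP_DEG,
               end_deg: float = DEFAULT_END_DEG) -> list[float]:
    """Arithmetic ray-fan angles, inclusive of both ends (default 3, 6, ..., 177)."""
    if not (0.0 < start_deg <= end_deg < 180.0):
        raise ConfigurationError(
            f"angles must satisfy 0 < start <= end < 180, got [{start_deg}, {end_deg}]")
    if step_deg <= 0.0:
        raise ConfigurationError("step_deg must be positive")
    n_steps = (end_deg - start_deg) / step_deg
    n_round = round(n_steps)
    if abs(n_steps - n_round) > 1e-9:
        raise ConfigurationError(
            f"(end - start) = {end_deg - start_deg} is not divisible by step {step_deg}")
    return [start_deg + i * step_deg for i in range(int(n_round) + 1)]


def place_origin(midline_a: Point2D, midline_b: Point2D,
                 baseline: BaselineSpec) -> OriginSpec:
    """Intersect the infinite midline through two points with the baseline segment.

    The intersection is the ray origin; the right-baseline length RB and the
    midline ratio r = RB / B are derived from it.
    """
    if midline_a.distance(midline_b) == 0.0:
        raise GeometryError("midline points coincide")
    p = baseline.left_terminus.as_array()
    r_vec = baseline.right_terminus.as_array() - p
    q = midline_a.as_array()
    s_vec = midline_b.as_array() - q

    def cross2(u, v):
        return float(u[0] * v[1] - u[1] * v[0])

    denom = cross2(r_vec, s_vec)
    if abs(denom) < 1e-15 * np.linalg.norm(r_vec) * np.linalg.norm(s_vec):
        raise GeometryError("midline is parallel to the baseline")
    t = cross2(q - p, s_vec) / denom
    if t < -ANCHOR_TOL or t > 1.0 + ANCHOR_TOL:
        raise GeometryError("midline intersects the baseline outside its segment")
    pt = p + np.clip(t, 0.0, 1.0) * r_vec
    return OriginSpec.from_origin(Point2D(float(pt[0]), float(pt[1])), baseline)


def midline_ratio(origin_spec: OriginSpec) -> float:
    """The midline ratio r = RB / B (0.5 when the origin is centred)."""
    return origin_spec.midline_ratio_r


def _ray_direction(theta_deg: float, datum: np.ndarray) -> np.ndarray:
    """Unit ray direction at ``theta_deg`` counterclockwise from the unit datum vector."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([c * datum[0] - s * datum[1], s * datum[0] + c * datum[1]])


def cast_ray(origin: Point2D, theta_deg: float, outline: SinusOutline,
             datum: Sequence[float] = (1.0, 0.0),
             merge_tol: float = MERGE_TOL) -> RayMeasurement:
    """Cast the half-line at ``theta_deg`` from ``origin`` and return the outermost crossing.

    ``datum`` is the unit 0-degree direction (origin toward the right baseline
    terminus); angles increase counterclockwise. All crossings with the
    outline's segments are found; crossings closer than ``merge_tol`` mm along
    the ray are merged, and the one at maximal distance is returned.
    """
    if not (0.0 < theta_deg < 180.0):
        raise ConfigurationError(f"ray angle {theta_deg} outside the open interval (0, 180)")
    d = _ray_direction(theta_deg, np.asarray(datum, dtype=float))
    o = origin.as_array()

    pts = outline.as_array()
    a = pts[:-1]
    seg = pts[1:] - a
    rel = a - o
    denom = d[0] * seg[:, 1] - d[1] * seg[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * seg[:, 1] - rel[:, 1] * seg[:, 0]) / denom
        u = (rel[:, 0] * d[1] - rel[:, 1] * d[0]) / denom
    ok = (np.abs(denom) > 1e-15) & (t > merge_tol) & (u >= -1e-12) & (u <= 1.0 + 1e-12)
    ts = np.sort(t[ok])
    if ts.size == 0:
        raise GeometryError(f"ray at {theta_deg} degrees does not intersect the outline")
    # merge crossings closer than merge_tol along the ray (vertex-exact hits)
    keep = np.concatenate([[True], np.diff(ts) > merge_tol])
    merged = ts[keep]
    L = float(merged[-1])
    hit = o + L * d
    return RayMeasurement(angle_theta=float(theta_deg),
                          intersection=Point2D(float(hit[0]), float(hit[1])),
                          line_length_L=L,
                          n_crossings=int(merged.size),
                          outermost_used=bool(merged.size > 1))


def _polygon_area(arr: np.ndarray) -> float:
    """Shoelace area of the region bounded by the arc and its closing chord (the baseline)."""
    x, y = arr[:, 0], arr[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def measure_profile(outline: SinusOutline, baseline: BaselineSpec, origin: OriginSpec,
                    angles: Sequence[float] | None = None,
                    perimeter: float | None = None) -> SinusProfile:
    """Measure the full ray-fan profile of an eligible outline.

    One :class:`RayMeasurement` per requested angle (default: the 59 angles at
    3-degree steps), in ascending order, in calibrated millimetres. The
    enclosed area (arc closed by the baseline chord) is computed by the
    shoelace formula; a raster-derived perimeter can be attached.
    """
    report = check_eligibility(outline, baseline, origin)
    if not report:
        raise EligibilityError("outline fails eligibility: " + "; ".join(report.messages))
    if angles is None:
        angles = ray_angles()
    angles = sorted(float(a) for a in angles)
    datum = (baseline.right_terminus.as_array() - origin.origin.as_array())
    datum = datum / np.linalg.norm(datum)
    measurements = []
    for theta in angles:
        try:
            measurements.append(cast_ray(origin.origin, theta, outline, datum=datum))
        except GeometryError as exc:
            raise GeometryError(f"profile measurement failed at {theta} degrees: {exc}") from exc
    return SinusProfile(outline_id=outline.id, baseline=baseline, origin=origin,
                        measurements=tuple(measurements),
                        area=_polygon_area(outline.as_array()),
                        perimeter=perimeter)


def line_length_from_perimeter(angle_perimeter_P: float, right_baseline_RB: float) -> float:
    """Movable-arm line length from an angle-tool export: L = P - RB.

    The angle tool records the fixed arm (origin to right terminus, length RB)
    plus the movable arm together as one perimeter P.
    """
    if right_baseline_RB < 0.0:
        raise GeometryError("right baseline length must be >= 0")
    if angle_perimeter_P < right_baseline_RB:
        from .errors import FormatError
        raise FormatError(
            f"angle perimeter {angle_perimeter_P} mm is shorter than the right baseline "
            f"{right_baseline_RB} mm; inconsistent export")
    return angle_perimeter_P - right_baseline_RB


def rotate_to_level(outline: SinusOutline, baseline: BaselineSpec, origin: OriginSpec,
                    angle_deg: float | None = None
                    ) -> tuple[SinusOutline, BaselineSpec, OriginSpec]:
    """Rigidly rotate outline + baseline about the origin by ``angle_deg``.

    With the default ``angle_deg=None`` the rotation levels the baseline to
    horizontal (rotates by minus its current tilt). All pairwise distances,
    hence B, RB and every profile length, are preserved.
    """
    if angle_deg is None:
        angle_deg = -baseline.tilt_deg
    if not math.isfinite(angle_deg):
        raise ConfigurationError("rotation angle must be finite")
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pivot = origin.origin.as_array()

    def rp(p: Point2D) -> Point2D:
        v = rot @ (p.as_array() - pivot) + pivot
        return Point2D(float(v[0]), float(v[1]))

    new_outline = SinusOutline(vertices=tuple(rp(p) for p in outline.vertices),
                               id=outline.id, scale_mm_per_px=outline.scale_mm_per_px)
    new_baseline = BaselineSpec(rp(baseline.left_terminus), rp(baseline.right_terminus))
    new_origin = OriginSpec.from_origin(origin.origin, new_baseline)
    return new_outline, new_baseline, new_origin


def check_eligibility(outline: SinusOutline, baseline: BaselineSpec, origin: OriginSpec,
                      anchor_tol: float = ANCHOR_TOL) -> EligibilityReport:
    """Check the eligibility rules for profile measurement.

    (a) the arc rises strictly above the baseline somewhere (the sinus extends
    superiorly past the supraorbital border); (b) the origin lies strictly
    between the termini (the sinus spans the midline); (c) the arc is a single
    connected chain anchored on the termini (the lobes touch). Eligibility
    guarantees every ray in (0, 180) degrees from the origin crosses the arc.
    """
    msgs = []
    arr = outline.as_array()
    left = baseline.left_terminus.as_array()
    d = baseline.direction
    # signed offset above the baseline line (positive = superior side)
    rel = arr - left
    offset = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    above = bool(np.any(offset > anchor_tol))
    if not above:
        msgs.append("no vertex rises above the baseline")

    rb = origin.right_baseline_RB
    interior = bool(anchor_tol < rb < baseline.length_B - anchor_tol)
    if not interior:
        msgs.append("origin is not strictly between the baseline termini")

    start_ok = outline.vertices[0].distance(baseline.left_terminus) <= anchor_tol
    end_ok = outline.vertices[-1].distance(baseline.right_terminus) <= anchor_tol
    continuous = bool(start_ok and end_ok)
    if not continuous:
        msgs.append("arc endpoints are not anchored on the baseline termini")

    return EligibilityReport(above_baseline=above, origin_interior=interior,
                             arc_continuous=continuous, messages=tuple(msgs))
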