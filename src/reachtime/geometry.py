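"""Body-relative 3D geometry for the reach-to-touch reaction-time test.

The test is calibrated to each participant's body: ``location_b`` is the
controller position held against the sternum, ``location_r`` the position
with the arm extended forward at shoulder height, and ``distance_d`` the
straight-line distance between them.  Nine stimulus locations are placed on
a sphere of radius ``distance_d`` around ``location_b`` — the central one
straight ahead, the others offset by ±30° in elevation and ±35° in azimuth.
Stimuli are 10-cm cubes whose front-face center sits on a grid location;
responses start from a 0.028-m base sphere around ``location_b``.

Coordinate frame convention: meters, +y up, +z participant-forward,
right-handed (so +x is the participant's right).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

BASE_RADIUS_M = 0.028
CUBE_EDGE_M = 0.10
ELEVATION_DEG = 30.0
AZIMUTH_DEG = 35.0

_UP = None  # set after Vec3 definition


class GeometryError(ValueError):
    """Invalid geometric input (degenerate calibration, zero direction, ...)."""


@dataclass(frozen=True)
class Vec3:
    """A point or direction in meters."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            c = getattr(self, name)
            if not math.isfinite(c):
                raise GeometryError(f"non-finite Vec3 component: {c!r}")
            object.__setattr__(self, name, float(c))

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def scale(self, k: float) -> "Vec3":
        return Vec3(k * self.x, k * self.y, k * self.z)

    def dot(self, other: "Vec3") -> float:
        return self.x * other.x + self.y * other.y + self.z * other.z

    def cross(self, other: "Vec3") -> "Vec3":
        return Vec3(
            self.y * other.z - self.z * other.y,
            self.z * other.x - self.x * other.z,
            self.x * other.y - self.y * other.x,
        )

    def norm(self) -> float:
        return math.sqrt(self.dot(self))

    def unit(self) -> "Vec3":
        n = self.norm()
        if n == 0.0:
            raise GeometryError("cannot normalize the zero vector")
        return self.scale(1.0 / n)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def __iter__(self) -> Iterator[float]:
        return iter((self.x, self.y, self.z))


UP = Vec3(0.0, 1.0, 0.0)
FORWARD = Vec3(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class Calibration:
    """Sternum anchor, extended-arm anchor, and the reach distance between them."""

    location_b: Vec3
    location_r: Vec3
    distance_d: float

    def __post_init__(self) -> None:
        if self.distance_d <= 0.0:
            raise GeometryError("distance_d must be positive")
        d = (self.location_r - self.location_b).norm()
        if abs(d - self.distance_d) > 1e-9:
            raise GeometryError(
                f"distance_d={self.distance_d} inconsistent with anchors (|r-b|={d})"
            )


def calibrate(location_b: Vec3, location_r: Vec3) -> Calibration:
    """Derive the calibration from the two recorded controller anchors.

    Raises :class:`GeometryError` if the anchors coincide.
    """
    d = (location_r - location_b).norm()
    if d <= 1e-12:
        raise GeometryError("invalid calibration: anchors coincide")
    return Calibration(location_b=location_b, location_r=location_r, distance_d=d)


# Row-major grid layout, 1 = upper-left ... 9 = lower-right, 5 central.
# Row selects elevation (+e, 0, -e); column selects azimuth (-a, 0, +a),
# negative azimuth being the participant's left.
_ROW_SIGN = (1.0, 0.0, -1.0)
_COL_SIGN = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class LocationGrid:
    """The nine stimulus locations, all at ``distance_d`` from ``location_b``."""

    locations: tuple[Vec3, ...]
    elevation_deg: float = ELEVATION_DEG
    azimuth_deg: float = AZIMUTH_DEG

    def __post_init__(self) -> None:
        if len(self.locations) != 9:
            raise GeometryError("grid must contain exactly 9 locations")

    def location(self, index: int) -> Vec3:
        """1-based lookup matching the numbered cube locations."""
        if not 1 <= index <= 9:
            raise GeometryError(f"location index {index} outside 1..9")
        return self.locations[index - 1]


def direction(elevation_deg: float, azimuth_deg: float) -> Vec3:
    """Unit direction (lateral, vertical, forward) for given angular offsets.

    ``dir(e, a) = (cos e sin a, sin e, cos e cos a)`` in the frame whose +z is
    the participant's forward and +y is up.  This composition keeps every
    grid location exactly at the calibrated reach distance.
    """
    e = math.radians(elevation_deg)
    a = math.radians(azimuth_deg)
    return Vec3(math.cos(e) * math.sin(a), math.sin(e), math.cos(e) * math.cos(a))


def build_grid(
    cal: Calibration,
    forward: Vec3 = FORWARD,
    elevation_deg: float = ELEVATION_DEG,
    azimuth_deg: float = AZIMUTH_DEG,
) -> LocationGrid:
    """Place the nine numbered locations around the participant.

    ``forward`` is the horizontal facing direction (its vertical component is
    ignored); locations are ``b + d * dir(e_i, a_i)`` expressed in the frame
    spanned by (right, up, forward).
    """
    if not (0.0 < elevation_deg < 90.0 and 0.0 < azimuth_deg < 90.0):
        raise GeometryError("grid angles must lie in (0, 90) degrees")
    flat = Vec3(forward.x, 0.0, forward.z)
    if flat.norm() <= 1e-12:
        raise GeometryError("forward direction must be nonzero in the horizontal plane")
    fwd = flat.unit()
    right = UP.cross(fwd)  # +x is the participant's right in the canonical frame

    b, d = cal.location_b, cal.distance_d
    locs = []
    for i in range(9):
        e = _ROW_SIGN[i // 3] * elevation_deg
        a = _COL_SIGN[i % 3] * azimuth_deg
        lat, vert, fw = direction(e, a)
        offset = right.scale(lat) + UP.scale(vert) + fwd.scale(fw)
        locs.append(b + offset.scale(d))
    return LocationGrid(
        locations=tuple(locs), elevation_deg=elevation_deg, azimuth_deg=azimuth_deg
    )


def in_base(p: Vec3, cal: Calibration, radius: float = BASE_RADIUS_M) -> bool:
    """True iff the controller is inside the base sphere (boundary inclusive)."""
    if radius <= 0.0:
        raise GeometryError("base radius must be positive")
    return (p - cal.location_b).norm() <= radius


@dataclass(frozen=True)
class CubeStimulus:
    """A colored cube whose front-face center sits on a grid location."""

    face_center: Vec3
    edge: float = CUBE_EDGE_M
    color: str = "yellow"

    def __post_init__(self) -> None:
        if self.edge <= 0.0:
            raise GeometryError("cube edge must be positive")


def cube_frame(inward: Vec3) -> tuple[Vec3, Vec3, Vec3]:
    """Orthonormal cube axes (depth, lateral, vertical) for a viewing
    direction; the cube body extends along ``inward``, behind the face."""
    w = inward.unit()
    u = UP.cross(w)
    if u.norm() <= 1e-9:  # cube straight above/below: any horizontal axis works
        u = Vec3(1.0, 0.0, 0.0)
    else:
        u = u.unit()
    return w, u, w.cross(u)


def cube_contains(p: Vec3, cube: CubeStimulus, inward: Vec3) -> bool:
    """Touch-volume membership: the full cube solid behind the front face.

    ``inward`` is the viewing direction from the participant toward the cube
    (b → face_center); the cube extends ``edge`` meters along it, away from
    the participant, and ±edge/2 laterally and vertically.
    """
    w, u, v = cube_frame(inward)
    dp = p - cube.face_center
    half = cube.edge / 2.0
    return (
        0.0 <= dp.dot(w) <= cube.edge
        and abs(dp.dot(u)) <= half
        and abs(dp.dot(v)) <= half
    )


@dataclass(frozen=True)
class MotionSpec:
    """Constant-velocity cube motion from one grid location toward another."""

    origin_index: int
    target_index: int
    speed: float  # m/s

    def __post_init__(self) -> None:
        if not (1 <= self.origin_index <= 9 and 1 <= self.target_index <= 9):
            raise GeometryError("motion indices must lie in 1..9")
        if self.target_index == self.origin_index:
            raise GeometryError("motion target must differ from origin")
        if self.speed <= 0.0:
            raise GeometryError("motion speed must be positive")


def cube_position_at(grid: LocationGrid, motion: MotionSpec, t: float) -> Vec3:
    """Front-face center of a moving cube ``t`` seconds after stimulus onset.

    The cube travels in a straight line at constant speed and keeps moving
    along that line past the target location until stimulus offset.
    """
    if t < 0.0:
        raise GeometryError("time since onset must be non-negative")
    origin = grid.location(motion.origin_index)
    target = grid.location(motion.target_index)
    step = (target - origin).unit().scale(motion.speed * t)
    return origin + step
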