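"""Beam / phantom / panel geometry for air-electron-stream experiments.

The experimental layout is a tilted acrylic phantom irradiated by a divergent
Co-60 beam on a 0.35 T MR-guided system, with film panels standing orthogonal
to the magnetic field on either side of the phantom.  The quantity this module
exists to compute is the *projected area*: the orthographic projection, along
the magnetic-field axis, of the beam's cross-section at the phantom entrance
or exit surface onto a panel plane.  That area is the geometric driver of the
out-of-field dose deposited by secondary electrons spiralling along the field.

Coordinate frame (fixed throughout the package):

* origin at the isocenter;
* ``+y`` along the magnetic field (couch to bore);
* ``+z`` vertically up;
* ``+x`` completes the right-handed frame.

The gantry rotates about ``y``; at gantry angle ``g`` (degrees) the beam
direction is ``(sin g, 0, -cos g)`` so a gantry-0 beam points straight down.
The phantom tilts about ``x`` so that its entrance-surface normal acquires a
``+y`` component; the *front* panel sits at ``y = +distance`` and the *end*
panel at ``y = -distance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "BeamSetup",
    "PhantomSetup",
    "PanelSetup",
    "ExperimentCondition",
    "Ray3",
    "Plane3",
    "FootprintPolygon",
    "GeometryError",
    "beam_corner_rays",
    "surface_plane",
    "ray_plane_intersection",
    "footprint_polygon",
    "projected_area",
    "enumerate_conditions",
    "condition_projected_area",
    "StudyConfig",
]

_UNIT_TOL = 1e-9
Y_AXIS = np.array([0.0, 1.0, 0.0])


class GeometryError(ValueError):
    """Raised for degenerate or unreachable geometric configurations."""


def _as_unit(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    norm = float(np.linalg.norm(arr))
    if abs(norm - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit vector (|v| = {norm:.3e})")
    return arr


@dataclass(frozen=True)
class BeamSetup:
    """A square divergent Co-60 beam.

    Parameters
    ----------
    gantry_angle : float
        Gantry angle in degrees, normalised to [0, 360).  The study used
        0, 30 and 330 degrees.
    field_size : float
        Side of the square field in cm, defined at the isocenter plane
        perpendicular to the central axis (6.3 or 12.6 in the study).
    sad : float
        Source-to-axis distance in cm (105 for the studied system).
    """

    gantry_angle: float
    field_size: float
    sad: float = 105.0

    def __post_init__(self) -> None:
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        if self.sad <= 0:
            raise ValueError("sad must be positive")
        object.__setattr__(self, "gantry_angle", float(self.gantry_angle) % 360.0)

    @property
    def direction(self) -> np.ndarray:
        """Unit beam direction (source towards isocenter)."""
        g = math.radians(self.gantry_angle)
        return np.array([math.sin(g), 0.0, -math.cos(g)])

    @property
    def source(self) -> np.ndarray:
        """Source position: isocenter - SAD * direction."""
        return -self.sad * self.direction


@dataclass(frozen=True)
class PhantomSetup:
    """Tilted rectangular acrylic phantom with its center of mass at isocenter.

    ``dimensions`` is (x, y, z) in the phantom's own frame in cm; the study
    phantom is 15 x 15 x 10 with the 10 cm side along the beam at zero tilt.
    ``tilt_angle`` (the "phantom angle") is the angle in degrees between the
    beam central axis at gantry 0 and the entrance-surface normal.
    """

    dimensions: tuple[float, float, float] = (15.0, 15.0, 10.0)
    tilt_angle: float = 0.0
    density: float = 1.18
    isocenter_at_center_of_mass: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_angle < 90.0):
            raise ValueError("tilt_angle must lie in [0, 90)")
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("all phantom dimensions must be positive")

    @property
    def normal(self) -> np.ndarray:
        """Outward entrance-surface normal (0, sin t, cos t)."""
        t = math.radians(self.tilt_angle)
        return np.array([0.0, math.sin(t), math.cos(t)])

    @property
    def rotation(self) -> np.ndarray:
        """Rotation matrix mapping phantom-frame vectors to the world frame."""
        t = math.radians(self.tilt_angle)
        c, s = math.cos(t), math.sin(t)
        # rotation about +x taking the phantom +z axis onto (0, sin t, cos t)
        return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])

    def contains(self, points: np.ndarray, pad: float = 0.0) -> np.ndarray:
        """Vectorised inside-box test for world-frame ``points`` (..., 3)."""
        local = np.asarray(points, dtype=float) @ self.rotation
        half = np.asarray(self.dimensions) / 2.0 + pad
        return np.all(np.abs(local) <= half, axis=-1)


@dataclass(frozen=True)
class PanelSetup:
    """Film panel parallel to the CAX plane and orthogonal to the B field."""

    side: Literal["front", "end"]
    distance: float
    extent: tuple[float, float] = (30.0, 30.0)
    pixel_size: float = 1.36  # mm

    def __post_init__(self) -> None:
        if self.side not in ("front", "end"):
            raise ValueError("panel side must be 'front' or 'end'")
        if self.distance <= 0:
            raise ValueError("panel distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def y(self) -> float:
        """Panel plane coordinate: front at +distance, end at -distance."""
        return self.distance if self.side == "front" else -self.distance


@dataclass(frozen=True)
class ExperimentCondition:
    """One of the study's setup combinations."""

    beam: BeamSetup
    phantom: PhantomSetup
    panel: PanelSetup
    prescription_dose: float = 300.0  # cGy

    def __post_init__(self) -> None:
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")

    def label(self) -> str:
        return (
            f"tilt{self.phantom.tilt_angle:g}_fs{self.beam.field_size:g}_"
            f"g{self.beam.gantry_angle:g}_d{self.panel.distance:g}_{self.panel.side}"
        )


@dataclass(frozen=True)
class Ray3:
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        _as_unit(self.direction, "ray direction")

    @property
    def o(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class Plane3:
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        _as_unit(self.normal, "plane normal")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(self.normal, dtype=float)


@dataclass(frozen=True)
class FootprintPolygon:
    """Planar polygon where the beam pyramid meets a phantom surface plane."""

    vertices: tuple[tuple[float, float, float], ...]
    plane: Plane3
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        v = self.array
        off = (v - self.plane.p) @ self.plane.n
        if np.max(np.abs(off)) > 1e-6:
            raise ValueError("polygon vertices are not on the stated plane")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def planar_area(self) -> float:
        """Area of the polygon within its own plane (3D shoelace)."""
        v = self.array
        cross_sum = np.zeros(3)
        for i in range(len(v)):
            cross_sum += np.cross(v[i], v[(i + 1) % len(v)])
        return 0.5 * abs(float(cross_sum @ self.plane.n))


FieldPlane = Literal["transverse", "bev"]


def beam_corner_rays(
    beam: BeamSetup, field_plane: FieldPlane = "transverse"
) -> tuple[Ray3, Ray3, Ray3, Ray3]:
    """Rays from the source through the four field corners at the isocenter plane.

    ``field_plane`` selects where the square field is drawn:

    * ``"transverse"`` (default) -- on the fixed horizontal plane ``z = 0``
      through the isocenter, with edges along ``x`` and ``y``.  This is the
      package's calibrated convention: it reproduces the published projected
      beam-footprint areas across gantry angles (see the methods note).
    * ``"bev"`` -- on the plane through the isocenter perpendicular to the
      central axis (beam's-eye-view), the standard collimation convention.

    The two coincide at gantry 0.  Corner ordering traces a simple
    quadrilateral: (+e1,+e2), (-e1,+e2), (-e1,-e2), (+e1,-e2).
    """
    d = beam.direction
    src = beam.source
    e1 = Y_AXIS
    if field_plane == "bev":
        e2 = np.cross(d, e1)
    elif field_plane == "transverse":
        if abs(d[2]) < 1e-9:
            raise GeometryError(
                "transverse field plane is degenerate for a horizontal beam"
            )
        e2 = np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError("field_plane must be 'transverse' or 'bev'")
    h = beam.field_size / 2.0
    rays = []
    for a, b in ((h, h), (-h, h), (-h, -h), (h, -h)):
        corner = a * e1 + b * e2
        vec = corner - src
        vec = vec / np.linalg.norm(vec)
        rays.append(Ray3(tuple(src), tuple(vec)))
    return tuple(rays)


def surface_plane(
    phantom: PhantomSetup, which: Literal["entrance", "exit"]
) -> Plane3:
    """Entrance or exit surface plane of the tilted phantom.

    The entrance plane passes through ``isocenter + (h/2) n`` and the exit
    plane through ``isocenter - (h/2) n`` with ``h`` the phantom thickness and
    ``n`` the tilted surface normal.  Both planes carry the entrance normal.
    """
    if which not in ("entrance", "exit"):
        raise ValueError("which must be 'entrance' or 'exit'")
    h = phantom.dimensions[2] / 2.0
    n = phantom.normal
    sign = 1.0 if which == "entrance" else -1.0
    return Plane3(tuple(sign * h * n), tuple(n))


_MISS = None


def ray_plane_intersection(ray: Ray3, plane: Plane3) -> np.ndarray | None:
    """Forward intersection point, or ``None`` on a miss.

    A miss (returned distinctly, not raised) occurs when the ray is parallel
    to the plane within 1e-12 or the intersection lies behind the origin.
    """
    denom = float(ray.d @ plane.n)
    if abs(denom) < 1e-12:
        return _MISS
    t = float((plane.p - ray.o) @ plane.n) / denom
    if t <= 0:
        return _MISS
    return ray.o + t * ray.d


def _face_axes(phantom: PhantomSetup) -> tuple[np.ndarray, np.ndarray]:
    """In-plane axes of the entrance/exit faces (phantom x and y edges)."""
    rot = phantom.rotation
    return rot @ np.array([1.0, 0.0, 0.0]), rot @ np.array([0.0, 1.0, 0.0])


def footprint_polygon(
    condition: ExperimentCondition,
    which: Literal["entrance", "exit"],
    clip_to_phantom: bool = False,
    field_plane: FieldPlane = "transverse",
) -> FootprintPolygon:
    """Beam footprint on a phantom surface plane.

    The four corner rays are intersected with the requested surface plane.
    With ``clip_to_phantom`` the quadrilateral is intersected with the
    physical face rectangle (15 x 15 cm).  The default is *unclipped*: at the
    exit side the beam cross-section lives on the (larger) support surface
    beneath the phantom, and the published areas are reproduced without
    clipping, so clipping is kept as a sensitivity option.
    """
    if condition.beam.field_size <= 1e-12:
        raise GeometryError("zero field size gives a degenerate footprint")
    plane = surface_plane(condition.phantom, which)
    pts = []
    for i, ray in enumerate(beam_corner_rays(condition.beam, field_plane)):
        p = ray_plane_intersection(ray, plane)
        if p is None:
            raise GeometryError(
                f"corner ray {i} does not intersect the {which} plane "
                "forward of the source (grazing incidence)"
            )
        pts.append(p)
    if not clip_to_phantom:
        return FootprintPolygon(tuple(map(tuple, pts)), plane, clipped=False)

    # clip in the face's own (a, b) coordinates
    u, v = _face_axes(condition.phantom)
    center = plane.p
    ab = np.array([[(p - center) @ u, (p - center) @ v] for p in pts])
    hx = condition.phantom.dimensions[0] / 2.0
    hy = condition.phantom.dimensions[1] / 2.0
    quad = _ShapelyPolygon(ab)
    face = _ShapelyPolygon([(-hx, -hy), (hx, -hy), (hx, hy), (-hx, hy)])
    inter = quad.intersection(face)
    if inter.is_empty or inter.area < 1e-9:
        raise GeometryError("footprint misses the phantom face entirely")
    coords = np.asarray(inter.exterior.coords)[:-1]
    verts = [tuple(center + a * u + b * v) for a, b in coords]
    return FootprintPolygon(tuple(verts), plane, clipped=True)


def projected_area(poly: FootprintPolygon) -> float:
    """Area of the polygon's orthographic projection along the field axis (y).

    Computed two ways -- shoelace on the projected (x, z) vertices, and planar
    polygon area times ``|n . y|`` -- which agree to 1e-9 relative for planar
    polygons; the vertex-projection value is returned.
    """
    v = poly.array
    x, z = v[:, 0], v[:, 2]
    tilt_factor = abs(float(poly.plane.n @ Y_AXIS))
    if tilt_factor == 0.0:
        # plane normal exactly orthogonal to the field axis: the projection
        # degenerates to a line segment
        return 0.0
    shoelace = 0.5 * abs(float(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1))))
    alt = poly.planar_area() * tilt_factor
    scale = max(shoelace, alt, 1.0)
    if abs(shoelace - alt) > 1e-9 * scale:
        raise AssertionError(
            f"projected-area routes disagree: {shoelace!r} vs {alt!r}"
        )
    return shoelace


@dataclass(frozen=True)
class StudyConfig:
    """Enumeration grid for the study; defaults reproduce the 72 conditions."""

    tilt_angles: tuple[float, ...] = (10.0, 20.0, 30.0)
    field_sizes: tuple[float, ...] = (6.3, 12.6)
    gantry_angles: tuple[float, ...] = (0.0, 30.0, 330.0)
    distances: tuple[float, ...] = (10.0, 17.0)
    panel_sides: tuple[str, ...] = ("front", "end")
    sad: float = 105.0
    prescription_dose: float = 300.0
    phantom_dimensions: tuple[float, float, float] = (15.0, 15.0, 10.0)


def enumerate_conditions(config: StudyConfig | None = None) -> list[ExperimentCondition]:
    """Deterministic enumeration: tilt, then field size, then gantry, then
    distance, then panel side.  The default study yields 72 conditions
    (36 beam deliveries, two panels each)."""
    cfg = config or StudyConfig()
    out: list[ExperimentCondition] = []
    for tilt in cfg.tilt_angles:
        for fs in cfg.field_sizes:
            for gantry in cfg.gantry_angles:
                for dist in cfg.distances:
                    for side in cfg.panel_sides:
                        out.append(
                            ExperimentCondition(
                                beam=BeamSetup(gantry, fs, cfg.sad),
                                phantom=PhantomSetup(
                                    cfg.phantom_dimensions, tilt
                                ),
                                panel=PanelSetup(side, dist),  # type: ignore[arg-type]
                                prescription_dose=cfg.prescription_dose,
                            )
                        )
    return out


def condition_projected_area(
    condition: ExperimentCondition,
    clip_to_phantom: bool = False,
    field_plane: FieldPlane = "transverse",
) -> float:
    """Projected area for a condition, using the surface that feeds its panel.

    The front panel sees electrons leaving the entrance surface; the end panel
    sees electrons leaving the exit surface (at the support beneath the
    phantom), so the footprint plane follows the panel side.
    """
    which = "entrance" if condition.panel.side == "front" else "exit"
    return projected_area(
        footprint_polygon(condition, which, clip_to_phantom, field_plane)
    )
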