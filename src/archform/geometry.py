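"""Occlusal reference frame and arch measurements.

The pipeline measures every arch in a cast-intrinsic coordinate frame: the
transverse (XOY) plane coincides with the occlusal plane fitted through the
posterior cusp tips, and the mid-sagittal (YOZ) plane passes through the
interproximal contact point of the central incisors, perpendicular to the
occlusal plane.  All coordinates are millimetres; the frame is right-handed
with +z toward the crowns and +y anterior (toward the incisors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    """Raised when a geometric construction is degenerate."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DentalMesh:
    """Triangulated cast surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    jaw : {"maxilla", "mandible"}
    """

    vertices: np.ndarray
    faces: np.ndarray
    jaw: str = "mandible"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) < 4:
            raise GeometryError("mesh needs at least 4 three-dimensional vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("mesh vertices contain non-finite coordinates")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError("faces must be triangles (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face indices out of range")
        if self.jaw not in ("maxilla", "mandible"):
            raise GeometryError(f"unknown jaw label {self.jaw!r}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class Plane:
    """Plane ``normal . p = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = p - np.outer(self.signed_distance(p), self.normal)
        return out[0] if np.asarray(points).ndim == 1 else out


@dataclass(frozen=True)
class OcclusalFrame:
    """Rigid map from world to occlusal coordinates.

    ``p_frame = rotation @ (p_world - origin)``.  After the transform the
    occlusal plane is z=0 and the mid-sagittal plane is x=0.
    """

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise GeometryError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "origin", np.asarray(self.origin, float))

    def transform(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p - self.origin) @ self.rotation.T

    def inverse_transform(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return p @ self.rotation + self.origin


@dataclass(frozen=True)
class ArchMeasurements:
    """Arch depth (anteroposterior, y) and width (transverse, x) in mm."""

    depth: float
    width: float

    def __post_init__(self):
        if not (self.depth > 0 and self.width > 0):
            raise GeometryError("depth and width must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fit_occlusal_plane(cusp_points: np.ndarray, below: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through posterior cusp tips.

    Minimizes the sum of squared orthogonal distances.  ``below`` is an
    optional reference point on the cast-base side used to orient the normal
    toward the crowns; without it the normal is oriented toward +z.
    """
    pts = np.atleast_2d(np.asarray(cusp_points, float))
    if len(pts) < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    # collinear points leave the plane orientation undetermined
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise GeometryError("cusp points are collinear; plane undetermined")
    normal = vt[2]
    if below is not None:
        if normal @ (centroid - np.asarray(below, float)) < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    return Plane(normal=normal, offset=float(normal @ centroid))


def plane_fit_residual(plane: Plane, points: np.ndarray) -> float:
    """Sum of squared orthogonal distances from ``points`` to ``plane``."""
    return float(np.sum(plane.signed_distance(points) ** 2))


def build_occlusal_frame(
    plane: Plane,
    incisor_contact: np.ndarray,
    distal_left: np.ndarray,
    distal_right: np.ndarray,
) -> OcclusalFrame:
    """Build the occlusal coordinate frame.

    y-axis: in-plane direction from the midpoint of the two distal landmarks
    toward the incisor contact point (anterior).  z-axis: plane normal
    (crown side).  x-axis completes a right-handed frame.  Origin: orthogonal
    projection of the incisor contact onto the occlusal plane.
    """
    contact = np.asarray(incisor_contact, float)
    mid_distal = (np.asarray(distal_left, float) + np.asarray(distal_right, float)) / 2.0
    z = plane.normal / np.linalg.norm(plane.normal)
    y = contact - mid_distal
    y = y - (y @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise GeometryError("incisor contact projects onto the distal midpoint; y-axis undefined")
    y = y / ny
    x = np.cross(y, z)
    rotation = np.vstack([x, y, z])
    origin = plane.project(contact)
    return OcclusalFrame(origin=origin, rotation=rotation)


def _arm_distal_x(arm: np.ndarray, y_line: float) -> float:
    """x-coordinate where an arch arm meets the distal-transverse line.

    ``arm`` runs from the distal end toward the apex.  The distal-transverse
    line is y = y_line (the global minimum of the curve).  If the arm reaches
    the line the crossing/touching point is returned; an arm whose distal end
    stays above the line (asymmetric arch) contributes its distal endpoint.
    """
    ys = arm[:, 1]
    # exact touch (the line passes through the most distal points)
    imin = int(np.argmin(ys))
    if np.isclose(ys[imin], y_line, atol=1e-12 * max(1.0, abs(y_line))):
        # ties toward the distal end of the arm
        touch = np.flatnonzero(np.isclose(ys, ys[imin]))
        return float(arm[touch[0], 0])
    # crossing by linear interpolation (only possible if some point dips below)
    below = ys < y_line
    if below.any():
        i = int(np.flatnonzero(below)[0])
        if i == 0:
            return float(arm[0, 0])
        t = (y_line - ys[i - 1]) / (ys[i] - ys[i - 1])
        return float(arm[i - 1, 0] + t * (arm[i, 0] - arm[i - 1, 0]))
    # arm never reaches the line: the more mesial end defines nothing; use
    # the arm's distal endpoint (resolution for asymmetric distal ends)
    return float(arm[0, 0])


def measure_depth_width(curve_points: np.ndarray) -> ArchMeasurements:
    """Arch depth and width of an ordered occlusal-plane curve.

    The distal-transverse line is the line parallel to the x-axis through the
    most distal (minimum-y) curve point.  Width is the x-distance between the
    curve's two intersections with that line; depth is the y-distance from the
    curve's intersection with the mid-sagittal line (x = 0) down to the
    distal-transverse line.
    """
    pts = np.atleast_2d(np.asarray(curve_points, float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise GeometryError("need at least 3 ordered 2D points")
    xs, ys = pts[:, 0], pts[:, 1]
    if xs.min() > 0 or xs.max() < 0:
        raise GeometryError("curve lies entirely on one side of the mid-sagittal line")
    y_line = float(ys.min())
    apex = int(np.argmax(ys))
    left = pts[: apex + 1]          # distal end first
    right = pts[apex:][::-1]        # reorder so distal end first
    if len(left) < 2 or len(right) < 2:
        raise GeometryError("curve apex coincides with an endpoint; arms degenerate")
    x_left = _arm_distal_x(left, y_line)
    x_right = _arm_distal_x(right, y_line)
    width = abs(x_right - x_left)
    # mid-sagittal intersection
    sign_change = np.flatnonzero(xs[:-1] * xs[1:] <= 0)
    y0 = None
    for i in sign_change:
        if xs[i] == xs[i + 1]:
            continue
        t = (0.0 - xs[i]) / (xs[i + 1] - xs[i])
        y0 = ys[i] + t * (ys[i + 1] - ys[i])
        break
    if y0 is None:
        exact = np.flatnonzero(xs == 0)
        if len(exact) == 0:
            raise GeometryError("curve does not cross the mid-sagittal line")
        y0 = float(ys[exact[0]])
    depth = float(y0 - y_line)
    return ArchMeasurements(depth=depth, width=float(width))
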