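"""Elementary 3-D geometry used throughout the measurement pipeline.

Lines, planes and anatomical frames are thin immutable containers around
numpy arrays.  All lengths are millimetres, all angles degrees unless a
name says otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "Line3D",
    "Plane3D",
    "Frame",
    "unit",
    "projected_angle",
    "rotation_matrix",
]

_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric input (zero vectors, collinear landmarks...)."""


def unit(v, name: str = "vector") -> np.ndarray:
    """Return ``v`` normalised to unit length, raising on zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{name} has (near-)zero length")
    return v / n


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_deg`` (right-hand rule)."""
    a = unit(axis, "rotation axis")
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


@dataclass(frozen=True)
class Line3D:
    """Oriented line: a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction, "line direction"))

    def at(self, t: float) -> np.ndarray:
        return self.point + t * self.direction

    def reversed(self) -> "Line3D":
        return Line3D(self.point, -self.direction)

    def closest_point(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.at(float(np.dot(p - self.point, self.direction)))

    def distance_to(self, p) -> float:
        return float(np.linalg.norm(np.asarray(p, float) - self.closest_point(p)))


@dataclass(frozen=True)
class Plane3D:
    """Plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal, "plane normal"))

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if d.size > 1 else float(d[0])

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (u, v) with u x v = normal."""
        n = self.normal
        seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = unit(seed - np.dot(seed, n) * n)
        v = np.cross(n, u)
        return u, v

    def to_plane_coords(self, points) -> np.ndarray:
        u, v = self.basis()
        rel = np.atleast_2d(np.asarray(points, dtype=float)) - self.point
        return np.column_stack([rel @ u, rel @ v])

    def to_world(self, xy) -> np.ndarray:
        u, v = self.basis()
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = self.point + np.outer(xy[:, 0], u) + np.outer(xy[:, 1], v)
        return out[0] if out.shape[0] == 1 else out

    def project_vector(self, vec) -> np.ndarray:
        vec = np.asarray(vec, dtype=float)
        return vec - np.dot(vec, self.normal) * self.normal


@dataclass(frozen=True)
class Frame:
    """Anatomical reference frame with labelled orthonormal axes.

    ``anterior``, ``proximal`` and ``lateral`` are mutually orthogonal unit
    vectors.  For a right femur the triad (anterior, proximal, lateral) is
    right-handed; for a left femur it is left-handed because *lateral* is an
    anatomical (side-dependent) direction while handedness is kept by the
    (anterior, proximal, anterior x proximal) sub-triad.
    """

    origin: np.ndarray
    anterior: np.ndarray
    proximal: np.ndarray
    lateral: np.ndarray
    kind: str = "tabletop"
    side: str = "right"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for name in ("anterior", "proximal", "lateral"):
            object.__setattr__(self, name, unit(getattr(self, name), name))
        M = np.vstack([self.anterior, self.proximal, self.lateral])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise GeometryError("frame axes are not orthonormal")
        if self.side not in ("right", "left"):
            raise GeometryError(f"unknown side {self.side!r}")

    @property
    def medial(self) -> np.ndarray:
        return -self.lateral

    @property
    def axes(self) -> np.ndarray:
        """Rows: anterior, proximal, lateral."""
        return np.vstack([self.anterior, self.proximal, self.lateral])

    # view normals: the direction along which a 2-D radiographic view projects
    @property
    def axial_normal(self) -> np.ndarray:
        return self.proximal

    @property
    def sagittal_normal(self) -> np.ndarray:
        return self.lateral

    @property
    def ap_normal(self) -> np.ndarray:
        return self.anterior


def projected_angle(a, b, view_normal, sign_reference, min_inclination_deg: float = 1.0) -> float:
    """Signed angle (degrees) between two directions after projection on a view.

    Both directions are projected onto the plane perpendicular to
    ``view_normal``.  The angle is measured from ``b``'s projection to ``a``'s
    projection and lies in (-180, 180]; it is positive when ``a`` leans toward
    ``sign_reference`` (projected in-plane and orthogonalised against ``b``).

    Raises :class:`GeometryError` when either direction is within
    ``min_inclination_deg`` of the view normal, since the projection then
    degenerates.
    """
    n = unit(view_normal, "view normal")
    out = []
    for name, vec in (("a", a), ("b", b)):
        v = unit(vec, name)
        p = v - np.dot(v, n) * n
        if np.linalg.norm(p) < np.sin(np.radians(min_inclination_deg)):
            raise GeometryError(
                f"line {name!r} is within {min_inclination_deg} deg of the view normal"
            )
        out.append(unit(p))
    ap, bp = out
    r = np.asarray(sign_reference, dtype=float)
    r = r - np.dot(r, n) * n - np.dot(r, bp) * bp
    if np.linalg.norm(r) < 1e-9:
        # sign reference lies along b: fall back to the in-plane normal of b
        r = np.cross(n, bp)
    r = unit(r)
    return float(np.degrees(np.arctan2(np.dot(ap, r), np.dot(ap, bp))))
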