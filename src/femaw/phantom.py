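"""Parametric proximal-femur phantoms with closed-form ground-truth angles.

A phantom stands in for a CT surface reconstruction of the proximal femur.
It is the union of analytic primitives -- a spherical head, a waisted neck
of revolution, a cylindrical shaft, a greater-trochanter (GT) block whose
anterior face is an exact plane, and two posterior condylar bosses -- so
that the three angles the measurement pipeline reports (femoral anteversion
FA, neck-shaft angle NSA, and the anterior-wall AW angle of the GT) are
known exactly from the construction parameters.

Conventions (canonical right femur, "scanner" frame):

* +x anterior, +y proximal, +z lateral; units mm, angles degrees.
* The shaft axis is the y-axis; the posterior condylar line is parallel to z.
* FA > 0 means anteversion (neck rotated anteriorly), FA < 0 retroversion.
* AW > 0 means the anterior GT wall leans anteriorly going proximally.

Left femora are produced by mirroring across the x-y plane; anatomical
landmark labels (medial/lateral) follow the side, so all three angles are
side-invariant by construction.

The random seed only drives nuisance features (optional surface jitter and
the offset of the hip-centre hint landmark), never the analytic geometry.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import Frame, unit

__all__ = [
    "PhantomSpec",
    "LandmarkSet",
    "PhantomConstructionError",
    "build_phantom",
    "ground_truth_angles",
    "RESOLUTION_CLASSES",
]


class PhantomConstructionError(ValueError):
    """The requested dial settings do not yield a buildable femur."""


# triangulation density per resolution class:
# (icosphere subdivisions, revolve sections, cylinder sections)
RESOLUTION_CLASSES = {
    "coarse": (2, 36, 36),
    "medium": (3, 64, 64),
    "fine": (4, 96, 96),
}

# fixed construction constants (mm), chosen to be anatomically plausible for
# an adult femur; see docs/methods.md
_NECK_LENGTH = 55.0  # head centre to neck-base point on the shaft axis
_NECK_BASE_Y = -15.0  # neck base station on the shaft axis (GT top at y=0)
_NECK_BASE_RADIUS = 16.0
_SHAFT_TOP_Y = -5.0
_GT_Z = (6.0, 34.0)  # medio-lateral extent of the GT block
_GT_POSTERIOR_X = -16.0
_GT_ANTERIOR_REF = np.array([16.0, 0.0, 20.0])  # point on the anterior wall plane
_BOSS_RADIUS = 14.0
_CONDYLE_Z = 20.0
_CONDYLE_POSTERIOR_X = -26.0
_LT_BASE_Y = -40.0  # "base of the lesser trochanter" station on the shaft


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical landmarks consumed by the measurement pipeline.

    ``lesser_trochanter_base_level`` is a scalar station (mm) along the
    femur's oriented longitudinal axis, measured from the mesh centre of
    mass (see :func:`femaw.morphometry.longitudinal_axis`); all other
    entries are 3-vectors in mesh coordinates.
    """

    lateral_ridge_GT: np.ndarray
    lesser_trochanter_base_level: float
    medial_posterior_condyle: np.ndarray
    lateral_posterior_condyle: np.ndarray
    epicondyle_midpoint: np.ndarray
    hip_center_hint: np.ndarray | None = None

    def __post_init__(self):
        for name in (
            "lateral_ridge_GT",
            "medial_posterior_condyle",
            "lateral_posterior_condyle",
            "epicondyle_midpoint",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.hip_center_hint is not None:
            object.__setattr__(self, "hip_center_hint", np.asarray(self.hip_center_hint, dtype=float))
        if np.allclose(self.medial_posterior_condyle, self.lateral_posterior_condyle):
            raise ValueError("condyle landmarks must be distinct")

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Apply a 4x4 homogeneous transform to every point landmark."""
        M = np.asarray(matrix, dtype=float)

        def tp(p):
            return (M[:3, :3] @ p) + M[:3, 3]

        return LandmarkSet(
            lateral_ridge_GT=tp(self.lateral_ridge_GT),
            lesser_trochanter_base_level=self.lesser_trochanter_base_level,
            medial_posterior_condyle=tp(self.medial_posterior_condyle),
            lateral_posterior_condyle=tp(self.lateral_posterior_condyle),
            epicondyle_midpoint=tp(self.epicondyle_midpoint),
            hip_center_hint=None if self.hip_center_hint is None else tp(self.hip_center_hint),
        )

    def as_dict(self) -> dict:
        d = {
            "lateral_ridge_GT": self.lateral_ridge_GT.tolist(),
            "lesser_trochanter_base_level": float(self.lesser_trochanter_base_level),
            "medial_posterior_condyle": self.medial_posterior_condyle.tolist(),
            "lateral_posterior_condyle": self.lateral_posterior_condyle.tolist(),
            "epicondyle_midpoint": self.epicondyle_midpoint.tolist(),
        }
        if self.hip_center_hint is not None:
            d["hip_center_hint"] = self.hip_center_hint.tolist()
        return d


@dataclass(frozen=True)
class PhantomSpec:
    """Dial settings for one synthetic proximal femur.

    ``true_anteversion``, ``true_neck_shaft_angle`` and ``true_aw_angle``
    are the ground-truth FA / NSA / AW angles in degrees; the remaining
    fields size the primitives.  ``head_center`` may be given to translate
    the finished phantom so the head lands at a chosen position.
    """

    true_anteversion: float = 14.8
    true_neck_shaft_angle: float = 127.3
    true_aw_angle: float = 17.5
    head_radius: float = 24.0
    neck_narrowest_diameter: float = 28.0
    shaft_radius: float = 14.0
    shaft_length: float = 160.0
    gt_height: float = 30.0
    condyle_offset: tuple[float, float, float] = (0.0, -150.0, 0.0)
    head_center: tuple[float, float, float] | None = None
    side: str = "right"
    mesh_resolution: str = "medium"
    surface_noise_mm: float = 0.0
    hint_jitter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not -20.0 <= self.true_anteversion <= 45.0:
            raise PhantomConstructionError("true_anteversion outside [-20, 45] deg")
        if not 110.0 <= self.true_neck_shaft_angle <= 150.0:
            raise PhantomConstructionError("true_neck_shaft_angle outside [110, 150] deg")
        if not -5.0 <= self.true_aw_angle <= 45.0:
            raise PhantomConstructionError("true_aw_angle outside [-5, 45] deg")
        if self.head_radius <= self.neck_narrowest_diameter / 2.0:
            raise PhantomConstructionError("head_radius must exceed the neck waist radius")
        if self.mesh_resolution not in RESOLUTION_CLASSES:
            raise PhantomConstructionError(f"unknown mesh_resolution {self.mesh_resolution!r}")
        if self.side not in ("right", "left"):
            raise PhantomConstructionError(f"side must be 'right' or 'left', got {self.side!r}")
        if self.shaft_length < 60.0 + abs(_LT_BASE_Y):
            raise PhantomConstructionError("shaft too short to host the shaft-axis stations")


def _neck_direction(spec: PhantomSpec) -> np.ndarray:
    """Unit vector from the neck base toward the head centre (right femur).

    Built so that the axial projection (drop y) makes exactly FA with the
    condylar line and the AP projection (drop x) makes exactly NSA with the
    distal shaft direction.
    """
    fa = np.radians(spec.true_anteversion)
    beta = np.radians(spec.true_neck_shaft_angle - 90.0)
    return unit(np.array([np.tan(fa), np.tan(beta), -1.0]))


def _isb_axes(head_center: np.ndarray, epicondyle_mid: np.ndarray,
              medial_condyle: np.ndarray, lateral_condyle: np.ndarray):
    """Closed-form ISB-style femoral axes used by construction and checks."""
    p = unit(head_center - epicondyle_mid, "ISB proximal axis")
    lat = lateral_condyle - medial_condyle
    lat = unit(lat - np.dot(lat, p) * p, "ISB lateral axis")
    a = np.cross(p, lat)
    cue = epicondyle_mid - 0.5 * (medial_condyle + lateral_condyle)
    if np.dot(a, cue) < 0:
        a = -a
    return a, p, lat


def _anterior_wall_plane(spec: PhantomSpec, head_center: np.ndarray,
                         epicondyle_mid: np.ndarray, medial_condyle: np.ndarray,
                         lateral_condyle: np.ndarray) -> np.ndarray:
    """Unit normal of the GT anterior wall (canonical right-femur frame).

    The wall is the plane through ``_GT_ANTERIOR_REF`` spanned by the ISB
    lateral axis and the in-plane direction w that makes exactly
    ``true_aw_angle`` with the shaft axis on the ISB sagittal projection.
    Because the plane contains the sagittal view normal, *any* line in the
    wall projects onto the same sagittal line, so the measured AW angle is
    independent of the GT cut obliquity.
    """
    a_isb, _, l_isb = _isb_axes(head_center, epicondyle_mid, medial_condyle, lateral_condyle)
    shaft_proximal = np.array([0.0, 1.0, 0.0])
    p_in = unit(shaft_proximal - np.dot(shaft_proximal, l_isb) * l_isb)
    q = a_isb - np.dot(a_isb, p_in) * p_in - np.dot(a_isb, l_isb) * l_isb
    q = unit(q)
    g = np.radians(spec.true_aw_angle)
    w = np.cos(g) * p_in + np.sin(g) * q
    n = unit(np.cross(w, l_isb))
    if n[0] < 0:  # orient the normal anteriorly
        n = -n
    return n


def _hexahedron(corners: np.ndarray) -> trimesh.Trimesh:
    """Closed hexahedron from 8 corners ordered (bottom 4 CCW, top 4 CCW)."""
    faces = [
        [0, 2, 1], [0, 3, 2],  # bottom
        [4, 5, 6], [4, 6, 7],  # top
        [0, 1, 5], [0, 5, 4],
        [1, 2, 6], [1, 6, 5],
        [2, 3, 7], [2, 7, 6],
        [3, 0, 4], [3, 4, 7],
    ]
    m = trimesh.Trimesh(vertices=corners, faces=faces, process=False)
    m.fix_normals()
    if m.volume < 0:
        m.invert()
    return m


def _gt_block(spec: PhantomSpec, wall_normal: np.ndarray) -> trimesh.Trimesh:
    z0, z1 = _GT_Z
    y_top, y_bot = 0.0, -spec.gt_height
    ref = _GT_ANTERIOR_REF
    n = wall_normal

    def wall_x(y, z):
        # solve n . ((x, y, z) - ref) = 0 for x
        return ref[0] - (n[1] * (y - ref[1]) + n[2] * (z - ref[2])) / n[0]

    xa = {(y, z): wall_x(y, z) for y in (y_bot, y_top) for z in (z0, z1)}
    if min(xa.values()) <= _GT_POSTERIOR_X + 1.0:
        raise PhantomConstructionError(
            "anterior GT wall would pass behind the posterior face; "
            "reduce |true_aw_angle| or gt_height"
        )
    corners = np.array([
        [_GT_POSTERIOR_X, y_bot, z0],
        [xa[(y_bot, z0)], y_bot, z0],
        [xa[(y_bot, z1)], y_bot, z1],
        [_GT_POSTERIOR_X, y_bot, z1],
        [_GT_POSTERIOR_X, y_top, z0],
        [xa[(y_top, z0)], y_top, z0],
        [xa[(y_top, z1)], y_top, z1],
        [_GT_POSTERIOR_X, y_top, z1],
    ])
    return _hexahedron(corners)


def _neck_mesh(spec: PhantomSpec, head_center: np.ndarray, d_head: np.ndarray,
               sections: int) -> trimesh.Trimesh:
    r_head = spec.head_radius
    r_waist = spec.neck_narrowest_diameter / 2.0
    t0 = r_head - 4.0  # start buried inside the head sphere
    t_waist = r_head + 6.0  # narrowest station, clear of the head surface
    r_start = min(_NECK_BASE_RADIUS, 0.95 * r_head)
    profile = np.array([
        [0.0, t0],
        [r_start, t0],
        [r_waist, t_waist],
        [_NECK_BASE_RADIUS, _NECK_LENGTH],
        [0.0, _NECK_LENGTH],
    ])
    m = trimesh.creation.revolve(profile, sections=sections)
    # map +z (revolve axis) onto the head->base direction, origin at head centre
    T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], -d_head)
    T = np.asarray(T, dtype=float)
    T[:3, 3] = head_center
    m.apply_transform(T)
    return m


def build_phantom(spec: PhantomSpec) -> tuple[trimesh.Trimesh, LandmarkSet]:
    """Build the phantom surface and its landmark set.

    Returns a watertight :class:`trimesh.Trimesh` (mm) and the
    :class:`LandmarkSet` the measurement pipeline needs.  Identical specs
    (including the seed) produce byte-identical vertex arrays.
    """
    rng = np.random.default_rng(spec.seed)
    subdiv, rev_sections, cyl_sections = RESOLUTION_CLASSES[spec.mesh_resolution]

    d_head = _neck_direction(spec)
    base = np.array([0.0, _NECK_BASE_Y, 0.0])
    head_center = base + _NECK_LENGTH * d_head

    if head_center[2] + spec.head_radius > _GT_Z[0] - 2.0:
        raise PhantomConstructionError("head sphere would collide with the GT block")
    if head_center[1] - spec.head_radius < _NECK_BASE_Y - 30.0:
        raise PhantomConstructionError("neck would not attach to the shaft")

    epicondyle_mid = np.asarray(spec.condyle_offset, dtype=float)
    medial_condyle = epicondyle_mid + np.array([_CONDYLE_POSTERIOR_X, 0.0, -_CONDYLE_Z])
    lateral_condyle = epicondyle_mid + np.array([_CONDYLE_POSTERIOR_X, 0.0, _CONDYLE_Z])

    wall_normal = _anterior_wall_plane(spec, head_center, epicondyle_mid,
                                       medial_condyle, lateral_condyle)

    head = trimesh.creation.icosphere(subdivisions=subdiv, radius=spec.head_radius)
    head.apply_translation(head_center)

    neck = _neck_mesh(spec, head_center, d_head, rev_sections)

    shaft_h = _SHAFT_TOP_Y + spec.shaft_length
    shaft = trimesh.creation.cylinder(radius=spec.shaft_radius, height=shaft_h,
                                      sections=cyl_sections)
    R = trimesh.transformations.rotation_matrix(np.pi / 2.0, [1.0, 0.0, 0.0])
    shaft.apply_transform(R)
    shaft.apply_translation([0.0, _SHAFT_TOP_Y - shaft_h / 2.0, 0.0])

    block = _gt_block(spec, wall_normal)

    bosses = []
    for cz in (-_CONDYLE_Z, _CONDYLE_Z):
        b = trimesh.creation.icosphere(subdivisions=2, radius=_BOSS_RADIUS)
        b.apply_translation(epicondyle_mid + np.array([_CONDYLE_POSTERIOR_X + _BOSS_RADIUS, 0.0, cz]))
        bosses.append(b)

    mesh = trimesh.util.concatenate([head, neck, shaft, block] + bosses)

    if spec.surface_noise_mm > 0:
        mesh.vertices += rng.normal(scale=spec.surface_noise_mm, size=mesh.vertices.shape)

    # lateral ridge: midpoint of the superolateral edge of the GT block top
    n = wall_normal
    ref = _GT_ANTERIOR_REF
    x_ant_top = ref[0] - (n[1] * (0.0 - ref[1]) + n[2] * (_GT_Z[1] - ref[2])) / n[0]
    ridge = np.array([0.5 * (_GT_POSTERIOR_X + x_ant_top), 0.0, _GT_Z[1]])
    lt_base_point = np.array([0.0, _LT_BASE_Y, 0.0])

    hint = head_center.copy()
    if spec.hint_jitter_mm > 0:
        offset = rng.normal(size=3)
        hint = head_center + spec.hint_jitter_mm * offset / max(np.linalg.norm(offset), 1.0)

    if spec.side == "left":
        mirror = np.diag([1.0, 1.0, -1.0, 1.0])
        mesh.apply_transform(mirror)  # trimesh flips winding for negative determinants
        head_center = head_center * [1, 1, -1]
        ridge = ridge * [1, 1, -1]
        lt_base_point = lt_base_point * [1, 1, -1]
        epicondyle_mid = epicondyle_mid * [1, 1, -1]
        medial_condyle = medial_condyle * [1, 1, -1]
        lateral_condyle = lateral_condyle * [1, 1, -1]
        hint = hint * [1, 1, -1]

    if spec.head_center is not None:
        delta = np.asarray(spec.head_center, dtype=float) - head_center
        mesh.apply_translation(delta)
        head_center = head_center + delta
        ridge = ridge + delta
        lt_base_point = lt_base_point + delta
        epicondyle_mid = epicondyle_mid + delta
        medial_condyle = medial_condyle + delta
        lateral_condyle = lateral_condyle + delta
        hint = hint + delta

    mesh.metadata["frame_label"] = "scanner"
    mesh.metadata["side"] = spec.side

    from .morphometry import longitudinal_axis  # deferred: avoids an import cycle

    com, u_prox = longitudinal_axis(mesh, distal_point=epicondyle_mid)
    lt_level = float(np.dot(lt_base_point - com, u_prox))

    landmarks = LandmarkSet(
        lateral_ridge_GT=ridge,
        lesser_trochanter_base_level=lt_level,
        medial_posterior_condyle=medial_condyle,
        lateral_posterior_condyle=lateral_condyle,
        epicondyle_midpoint=epicondyle_mid,
        hip_center_hint=hint,
    )
    return mesh, landmarks


def ground_truth_angles(spec: PhantomSpec):
    """Ground-truth (FA, NSA, AW) for a spec, as an AngleSet.

    These are the dial values themselves: the construction guarantees that
    the projections defining each angle reproduce the dials exactly.
    """
    from .morphometry import AngleSet

    return AngleSet(
        fa=float(spec.true_anteversion),
        nsa=float(spec.true_neck_shaft_angle),
        aw=float(spec.true_aw_angle),
        side=spec.side,
    )
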