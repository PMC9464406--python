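"""Geometric measurement of femoral anteversion, neck-shaft and AW angles.

The pipeline mirrors how the angles are measured on CT surface models:

1. the femoral head centre is the centre of the best-fit sphere;
2. the neck axis joins the head centre to the centroid of the narrowest
   neck cross-section (found by iteratively scanning cutting planes);
3. the shaft axis joins the medullary-canal centres of two transverse
   sections, at the base of the lesser trochanter and 5 cm further distal;
4. a greater-trochanter (GT) osteotomy is simulated: the cut plane passes
   5 mm distal to the lateral ridge of the GT and is tilted until the
   resected cap has a maximum thickness of 10 mm;
5. the line tangential to the (nearly flat) anterior wall of the cut
   surface is fitted, and the three angles are read off as projections:
   FA on the axial view against the posterior condylar line, NSA on the
   anteroposterior (tabletop) view, AW on the sagittal view of an
   ISB-style femoral frame.

All operations take plain :class:`trimesh.Trimesh` surfaces (mm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.polygon import orient as shapely_orient
import trimesh
from scipy.optimize import least_squares

from .geometry import Frame, GeometryError, Line3D, Plane3D, projected_angle, unit

__all__ = [
    "AngleSet",
    "MeasureConfig",
    "MorphometryError",
    "SphereFitError",
    "SectionError",
    "CutError",
    "WallFitError",
    "NeckSection",
    "Contour",
    "WallLineResult",
    "fit_sphere",
    "select_head_points",
    "narrowest_neck_section",
    "neck_axis",
    "longitudinal_axis",
    "shaft_axis",
    "simulate_gt_cut",
    "anterior_wall_line",
    "build_tabletop_frame",
    "build_isb_frame",
    "measure_femur",
]


class MorphometryError(RuntimeError):
    """A measurement stage failed; the message names the stage."""


class SphereFitError(MorphometryError):
    pass


class SectionError(MorphometryError):
    pass


class CutError(MorphometryError):
    pass


class WallFitError(MorphometryError):
    pass


@dataclass(frozen=True)
class AngleSet:
    """Per-femur angle measurements in degrees.

    ``fa``: anteversion (+) / retroversion (-); ``nsa``: neck-shaft angle in
    (0, 180); ``aw``: anterior-wall angle, positive when the wall leans
    anteriorly going proximally.
    """

    fa: float
    nsa: float
    aw: float
    side: str = "right"
    diagnostics: dict = field(default_factory=dict, compare=False, repr=False)

    def as_row(self) -> dict:
        return {"side": self.side, "fa_deg": self.fa, "nsa_deg": self.nsa, "aw_deg": self.aw}


@dataclass
class MeasureConfig:
    """Tunables of the measurement pipeline (defaults are the study setup)."""

    cut_offset_mm: float = 5.0           # entry point below the GT lateral ridge
    cap_thickness_mm: float = 10.0       # target maximum thickness of the resected cap
    thickness_tol_mm: float = 0.1
    max_tilt_deg: float = 60.0
    wall_cone_deg: float = 60.0          # "anterior" selection cone for wall vertices
    wall_min_arc_mm: float = 5.0
    neck_scan_length_mm: float = 20.0
    neck_scan_step_mm: float = 0.5
    neck_tol_mm: float = 0.1
    neck_max_iter: int = 10
    head_search_radius_mm: float = 40.0
    axial_view: str = "shaft"            # "shaft": axial plane is perpendicular to the shaft
    scanner_axes: np.ndarray | None = None  # rows anterior/proximal/lateral, if known
    aw_sweep_offsets_mm: tuple = ()      # extra cut levels for the optional AW sweep


# ---------------------------------------------------------------------------
# sphere fitting


def fit_sphere(points) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through ``points``.

    An algebraic (linear) solve gives the starting values and a geometric
    Levenberg-Marquardt refinement minimises the orthogonal distances.
    Returns ``(center, radius, rms_residual)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 10:
        raise SphereFitError("need at least 10 points in 3-D")
    spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-9 * max(spread[0], 1.0):
        raise SphereFitError("points are coplanar; sphere fit is singular")

    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    out = least_squares(resid, x0=[*c0, r0], method="lm")
    center, radius = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def select_head_points(mesh: trimesh.Trimesh, hint, search_radius_mm: float = 40.0,
                       bands_mm=(3.0, 1.5, 0.8, 0.5)) -> np.ndarray:
    """Vertices on the femoral-head sphere near the ``hint`` position.

    Starts from all vertices within ``search_radius_mm`` of the hint and
    iteratively keeps those whose distance to the current sphere fit lies
    within a shrinking band.  The hint must be within a few mm of the true
    head centre.
    """
    hint = np.asarray(hint, dtype=float)
    v = mesh.vertices
    d = np.linalg.norm(v - hint, axis=1)
    cand = v[d < search_radius_mm]
    if len(cand) < 10:
        raise SphereFitError("no mesh vertices near the hip-centre hint")
    r_est = float(np.percentile(np.linalg.norm(cand - hint, axis=1), 10))
    center = hint
    keep = cand
    for band in bands_mm:
        dist = np.linalg.norm(cand - center, axis=1)
        keep = cand[np.abs(dist - r_est) < band]
        if len(keep) < 10:
            raise SphereFitError("head-surface point selection collapsed")
        center, r_est, _ = fit_sphere(keep)
    return keep


# ---------------------------------------------------------------------------
# planar cross-sections


def _section_polygons(mesh: trimesh.Trimesh, plane: Plane3D):
    """Closed cross-section contours of ``mesh`` in ``plane``.

    Returns a list of ``(shapely_polygon, points3d)`` tuples, one per
    closed loop, with 2-D coordinates in the plane's deterministic basis.
    """
    path = mesh.section(plane_origin=plane.point, plane_normal=plane.normal)
    if path is None:
        return []
    out = []
    for loop in path.discrete:
        if len(loop) < 4 or not np.allclose(loop[0], loop[-1]):
            continue
        xy = plane.to_plane_coords(loop)
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area <= 0:
            continue
        out.append((poly, loop))
    return out


def _polygon_containing(polys, xy=(0.0, 0.0)):
    """Polygon containing the 2-D point whose centroid is nearest it, or None.

    Centroid proximity disambiguates overlapping contours: the structure of
    interest (neck tube, medullary canal) is centred on the query point,
    while glancing cuts through neighbouring primitives are not.
    """
    pt = Point(*xy)
    hits = [pair for pair in polys if pair[0].contains(pt)]
    if not hits:
        return None
    return min(hits, key=lambda pair: (round(pair[0].centroid.distance(pt), 3),
                                       pair[0].area))


@dataclass(frozen=True)
class NeckSection:
    midpoint: np.ndarray
    area: float
    plane: Plane3D
    iterations: int
    unique_minimum: bool


def narrowest_neck_section(mesh: trimesh.Trimesh, head_center, initial_direction, *,
                           scan_start_mm: float | None = None,
                           scan_length_mm: float = 20.0,
                           step_mm: float = 0.5,
                           tol_mm: float = 0.1,
                           max_iter: int = 10) -> NeckSection:
    """Centroid of the narrowest neck cross-section.

    Scans cutting planes perpendicular to the current axis estimate at
    stations ``scan_start_mm`` to ``scan_start_mm + scan_length_mm`` from
    the head centre, takes the minimal-area contour (the one enclosing the
    axis), and re-estimates the axis head-centre -> centroid until the
    centroid moves less than ``tol_mm`` (at most ``max_iter`` rounds).

    A near-constant area profile (e.g. a cylindrical neck) is flagged via
    ``unique_minimum=False`` and resolved to the mid-station centroid.
    """
    head_center = np.asarray(head_center, dtype=float)
    d = unit(initial_direction, "initial neck direction")
    if scan_start_mm is None:
        scan_start_mm = 22.0
    stations = np.arange(scan_start_mm, scan_start_mm + scan_length_mm + 1e-9, step_mm)

    mid = None
    area = np.nan
    plane = None
    unique = True
    for it in range(1, max_iter + 1):
        areas = np.full(len(stations), np.nan)
        cents = np.full((len(stations), 3), np.nan)
        for i, s in enumerate(stations):
            pl = Plane3D(head_center + s * d, d)
            hit = _polygon_containing(_section_polygons(mesh, pl))
            if hit is None:
                continue
            poly, _ = hit
            areas[i] = poly.area
            c = poly.centroid
            cents[i] = pl.to_world([c.x, c.y])
        valid = np.isfinite(areas)
        if valid.sum() < 3:
            raise SectionError("no closed neck contour found along the scan range")
        rel_range = (np.nanmax(areas) - np.nanmin(areas)) / max(np.nanmin(areas), 1e-12)
        if rel_range < 1e-3:
            # degenerate (constant-radius) neck: no unique minimum
            unique = False
            idx = np.flatnonzero(valid)
            i_mid = idx[len(idx) // 2]
            mid, area = cents[i_mid], float(areas[i_mid])
            plane = Plane3D(mid, d)
            break
        i_min = int(np.nanargmin(areas))
        s_best = stations[i_min]
        # parabolic refinement of the minimal station
        if 0 < i_min < len(stations) - 1 and valid[i_min - 1] and valid[i_min + 1]:
            y0, y1, y2 = areas[i_min - 1], areas[i_min], areas[i_min + 1]
            denom = y0 - 2 * y1 + y2
            if denom > 1e-12:
                s_best = s_best + 0.5 * step_mm * (y0 - y2) / denom
        pl = Plane3D(head_center + s_best * d, d)
        hit = _polygon_containing(_section_polygons(mesh, pl))
        if hit is None:
            pl = Plane3D(head_center + stations[i_min] * d, d)
            hit = _polygon_containing(_section_polygons(mesh, pl))
            if hit is None:
                raise SectionError("refined neck section lost the contour")
        poly, _ = hit
        c = poly.centroid
        new_mid = pl.to_world([c.x, c.y])
        area = float(poly.area)
        plane = Plane3D(new_mid, d)
        if mid is not None and np.linalg.norm(new_mid - mid) < tol_mm:
            mid = new_mid
            break
        mid = new_mid
        d = unit(mid - head_center)
    return NeckSection(midpoint=mid, area=area, plane=plane, iterations=it,
                       unique_minimum=unique)


def neck_axis(head_center, neck_midpoint) -> Line3D:
    """Neck axis through the head centre and the narrowest-neck midpoint.

    The direction points from the head toward the neck (laterally).
    """
    head_center = np.asarray(head_center, dtype=float)
    neck_midpoint = np.asarray(neck_midpoint, dtype=float)
    if np.linalg.norm(neck_midpoint - head_center) <= 1.0:
        raise GeometryError("head centre and neck midpoint are closer than 1 mm")
    return Line3D(head_center, neck_midpoint - head_center)


# ---------------------------------------------------------------------------
# shaft axis


def longitudinal_axis(mesh: trimesh.Trimesh, distal_point=None) -> tuple[np.ndarray, np.ndarray]:
    """(centre of mass, proximal unit vector) of the femur's long axis.

    The direction is the principal axis of the vertex cloud; orientation is
    fixed so the ``distal_point`` (e.g. the epicondyle midpoint) projects
    negatively, or -- lacking one -- so the end with the larger radial
    spread (head and trochanter) is proximal.
    """
    v = mesh.vertices
    com = np.asarray(mesh.center_mass, dtype=float)
    _, _, vt = np.linalg.svd(v - v.mean(axis=0), full_matrices=False)
    u = unit(vt[0])
    if distal_point is not None:
        if np.dot(np.asarray(distal_point, float) - com, u) > 0:
            u = -u
    else:
        s = (v - com) @ u
        radial = np.linalg.norm((v - com) - np.outer(s, u), axis=1)
        upper = radial[s > np.median(s)].mean()
        lower = radial[s <= np.median(s)].mean()
        if upper < lower:
            u = -u
    return com, u


def shaft_axis(mesh: trimesh.Trimesh, lesser_troch_base_level: float, *,
               distal_point=None, spacing_mm: float = 50.0) -> Line3D:
    """Shaft axis from two transverse medullary-canal centres.

    The canal centre is taken as the cross-section centroid of the shaft
    contour at the stated station (mm along the oriented longitudinal axis,
    origin at the centre of mass) and at ``spacing_mm`` further distal.
    The returned line is oriented proximal -> distal.
    """
    com, u = longitudinal_axis(mesh, distal_point=distal_point)
    cents = []
    for level in (lesser_troch_base_level, lesser_troch_base_level - spacing_mm):
        pl = Plane3D(com + level * u, u)
        polys = _section_polygons(mesh, pl)
        if not polys:
            raise SectionError(f"no closed shaft contour at station {level:+.1f} mm")
        hit = _polygon_containing(polys)
        if hit is None:
            hit = min(polys, key=lambda pair: pair[0].centroid.distance(Point(0, 0)))
        poly, _ = hit
        c = poly.centroid
        cents.append(pl.to_world([c.x, c.y]))
    proximal_c, distal_c = cents
    return Line3D(proximal_c, distal_c - proximal_c)


# ---------------------------------------------------------------------------
# greater-trochanter cut and anterior wall


@dataclass(frozen=True)
class Contour:
    """Closed planar cross-section polygon (mm)."""

    plane: Plane3D
    points: np.ndarray  # (k, 3), closed loop, first == last
    tilt_deg: float = np.nan
    cap_thickness_mm: float = np.nan

    def to_2d(self) -> np.ndarray:
        return self.plane.to_plane_coords(self.points)


def _cap_thickness(mesh, normal, origin, ridge):
    """Max perpendicular thickness of the resected component nearest the ridge."""
    cap = trimesh.intersections.slice_mesh_plane(mesh, plane_normal=normal,
                                                 plane_origin=origin)
    if cap is None or len(cap.faces) == 0:
        return 0.0
    cap.merge_vertices()
    parts = cap.split(only_watertight=False)
    if len(parts) == 0:
        return 0.0
    part = min(parts, key=lambda p: np.min(np.linalg.norm(p.vertices - ridge, axis=1)))
    return float(np.max((part.vertices - origin) @ normal))


def simulate_gt_cut(mesh: trimesh.Trimesh, lateral_ridge, shaft: Line3D,
                    frame: Frame, *, cut_offset_mm: float = 5.0,
                    thickness_mm: float = 10.0, tol_mm: float = 0.1,
                    max_tilt_deg: float = 60.0) -> tuple[Plane3D, Contour]:
    """Simulated GT osteotomy plane and its cut-surface contour.

    The plane passes through the point ``cut_offset_mm`` distal to the
    lateral ridge (along the shaft axis) and is tilted about the
    anteroposterior axis -- dipping medially -- until the resected cap's
    maximum thickness, measured perpendicular to the plane, equals
    ``thickness_mm`` (binary search to ``tol_mm``).
    """
    ridge = np.asarray(lateral_ridge, dtype=float)
    entry = ridge + cut_offset_mm * shaft.direction  # shaft.direction is distal
    p_hat = -shaft.direction
    l_hat = frame.lateral

    def normal_at(tilt_deg):
        t = np.radians(tilt_deg)
        return unit(np.cos(t) * p_hat - np.sin(t) * l_hat)

    def f(tilt_deg):
        return _cap_thickness(mesh, normal_at(tilt_deg), entry, ridge)

    lo, hi = 0.0, max_tilt_deg
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > thickness_mm + tol_mm:
        raise CutError(
            f"cap already {f_lo:.2f} mm thick with an untilted plane "
            f"(target {thickness_mm} mm)"
        )
    if f_hi < thickness_mm - tol_mm:
        raise CutError(
            f"max thickness {f_hi:.2f} mm at {max_tilt_deg:.0f} deg tilt; "
            f"cannot reach {thickness_mm} mm"
        )
    tilt, thick = lo, f_lo
    for _ in range(60):
        tilt = 0.5 * (lo + hi)
        thick = f(tilt)
        if abs(thick - thickness_mm) <= tol_mm:
            break
        if thick < thickness_mm:
            lo = tilt
        else:
            hi = tilt
    plane = Plane3D(entry, normal_at(tilt))
    polys = _section_polygons(mesh, plane)
    if not polys:
        raise CutError("cut plane does not intersect the mesh")
    exy = plane.to_plane_coords(entry)[0]
    poly, loop = min(polys, key=lambda pair: pair[0].exterior.distance(Point(*exy)))
    contour = Contour(plane=plane, points=loop, tilt_deg=float(tilt),
                      cap_thickness_mm=float(thick))
    return plane, contour


@dataclass(frozen=True)
class WallLineResult:
    line: Line3D
    rms_mm: float
    arc_length_mm: float
    is_flat: bool


def anterior_wall_line(contour: Contour, frame: Frame, *, cone_deg: float = 60.0,
                       min_arc_mm: float = 5.0, sample_mm: float = 0.5,
                       flat_rms_mm: float = 0.2) -> WallLineResult:
    """Line tangential to the anterior wall of the GT cut surface.

    Boundary samples whose outward normal lies within ``cone_deg`` of the
    (in-plane) anterior direction form the anterior-wall arc; a total
    least-squares line is fitted to them and translated anteriorly so it is
    tangent at the most anterior sample.  The direction is oriented
    distal -> proximal.  ``rms_mm`` reports the wall's deviation from
    flatness; ``is_flat`` is False for e.g. a rounded wall, in which case
    the tangent at the apex is still returned.
    """
    plane = contour.plane
    poly = Polygon(plane.to_plane_coords(contour.points))
    if not poly.is_valid:
        poly = poly.buffer(0)
    poly = shapely_orient(poly, sign=1.0)  # CCW exterior
    ring = shapely.segmentize(poly.exterior, sample_mm)
    xy = np.asarray(ring.coords)[:-1]
    edges = np.roll(xy, -1, axis=0) - xy
    lengths = np.linalg.norm(edges, axis=1)
    ok = lengths > 1e-9
    xy, edges, lengths = xy[ok], edges[ok], lengths[ok]
    # outward normal of a CCW polygon: edge direction rotated -90 deg
    normals = np.column_stack([edges[:, 1], -edges[:, 0]]) / lengths[:, None]

    a_in3 = plane.project_vector(frame.anterior)
    if np.linalg.norm(a_in3) < 1e-6:
        raise WallFitError("anterior direction is perpendicular to the cut plane")
    u, v = plane.basis()
    a2 = unit(np.array([np.dot(a_in3, u), np.dot(a_in3, v)]))

    sel = normals @ a2 > np.cos(np.radians(cone_deg))
    arc = float(lengths[sel].sum())
    if arc < min_arc_mm:
        raise WallFitError(
            f"anterior wall arc is only {arc:.1f} mm (< {min_arc_mm} mm); "
            "wall not identifiable"
        )
    mids = xy[sel] + 0.5 * edges[sel]
    w = lengths[sel]
    mean = (mids * w[:, None]).sum(axis=0) / w.sum()
    X = (mids - mean) * np.sqrt(w)[:, None]
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    d2 = vt[0]
    n2 = np.array([-d2[1], d2[0]])
    resid = (mids - mean) @ n2
    rms = float(np.sqrt(np.average(resid**2, weights=w)))

    # tangency: translate through the most anterior selected sample
    ends = np.concatenate([xy[sel], xy[sel] + edges[sel]])
    apex = ends[np.argmax(ends @ a2)]

    d3 = unit(d2[0] * u + d2[1] * v)
    if np.dot(d3, frame.proximal) < 0:
        d3 = -d3
    p3 = plane.to_world(apex)
    return WallLineResult(line=Line3D(p3, d3), rms_mm=rms, arc_length_mm=arc,
                          is_flat=rms <= flat_rms_mm)


# ---------------------------------------------------------------------------
# frames


def _frame_from_directions(origin, proximal, lateral_raw, anterior_cue, kind) -> Frame:
    p = unit(proximal, "proximal axis")
    lat = np.asarray(lateral_raw, dtype=float)
    lat = lat - np.dot(lat, p) * p
    if np.linalg.norm(lat) < 1e-6:
        raise GeometryError("landmarks are collinear; cannot span a frame")
    lat = unit(lat)
    a = np.cross(p, lat)
    side = "right"
    if np.dot(a, anterior_cue) < 0:
        a, side = -a, "left"
    return Frame(origin=origin, anterior=a, proximal=p, lateral=lat, kind=kind, side=side)


def _anterior_cue(landmarks) -> np.ndarray:
    condyle_mid = 0.5 * (landmarks.medial_posterior_condyle + landmarks.lateral_posterior_condyle)
    return landmarks.epicondyle_midpoint - condyle_mid


def build_tabletop_frame(landmarks, scanner_axes=None, *, shaft: Line3D | None = None) -> Frame:
    """Tabletop (scanner-aligned) frame.

    With known ``scanner_axes`` (rows anterior/proximal/lateral) those are
    used directly, as for a supine, symmetrically positioned acquisition.
    Otherwise the frame is rebuilt from anatomy -- proximal along the shaft
    axis, lateral along the condylar line -- which coincides with the table
    axes for a canonically positioned femur and makes the measurement
    invariant under rigid motion of the mesh.
    """
    origin = landmarks.epicondyle_midpoint
    if scanner_axes is not None:
        ax = np.asarray(scanner_axes, dtype=float)
        return Frame(origin=origin, anterior=ax[0], proximal=ax[1], lateral=ax[2],
                     kind="tabletop")
    if shaft is None:
        raise GeometryError("tabletop frame needs scanner axes or a shaft axis")
    lat = landmarks.lateral_posterior_condyle - landmarks.medial_posterior_condyle
    return _frame_from_directions(origin, -shaft.direction, lat, _anterior_cue(landmarks),
                                  "tabletop")


def build_isb_frame(landmarks, head_center) -> Frame:
    """ISB-style femoral frame.

    Proximal axis from the epicondyle midpoint to the head centre; lateral
    axis along the posterior condylar line orthogonalised against it;
    anterior completes the triad (oriented by the epicondyle-vs-condyle
    anterior cue, which also determines the side).
    """
    head_center = np.asarray(head_center, dtype=float)
    lat = landmarks.lateral_posterior_condyle - landmarks.medial_posterior_condyle
    return _frame_from_directions(landmarks.epicondyle_midpoint,
                                  head_center - landmarks.epicondyle_midpoint,
                                  lat, _anterior_cue(landmarks), "ISB")


# ---------------------------------------------------------------------------
# full pipeline


def measure_femur(mesh: trimesh.Trimesh, landmarks, config: MeasureConfig | None = None) -> AngleSet:
    """Run the full measurement pipeline on one femur surface.

    Requires the landmark set to include ``hip_center_hint`` (an approximate
    head-centre position, within a few mm).  Errors from any stage are
    re-raised with the stage name prefixed.
    """
    cfg = config or MeasureConfig()

    def stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise MorphometryError(f"stage {name!r} failed: {e}") from e

    shaft = stage("shaft_axis", shaft_axis, mesh, landmarks.lesser_trochanter_base_level,
                  distal_point=landmarks.epicondyle_midpoint)

    if landmarks.hip_center_hint is None:
        raise MorphometryError("stage 'fit_sphere' failed: hip_center_hint landmark required")
    head_pts = stage("fit_sphere", select_head_points, mesh, landmarks.hip_center_hint,
                     cfg.head_search_radius_mm)
    head_center, head_radius, sphere_rms = stage("fit_sphere", fit_sphere, head_pts)

    # aim the initial neck direction at the shaft axis slightly distal to the ridge
    ridge_foot = shaft.closest_point(landmarks.lateral_ridge_GT)
    target = ridge_foot + 15.0 * shaft.direction
    neck = stage(
        "narrowest_neck_section", narrowest_neck_section, mesh, head_center,
        target - head_center,
        scan_start_mm=1.05 * head_radius,
        scan_length_mm=cfg.neck_scan_length_mm,
        step_mm=cfg.neck_scan_step_mm,
        tol_mm=cfg.neck_tol_mm,
        max_iter=cfg.neck_max_iter,
    )
    n_axis = stage("neck_axis", neck_axis, head_center, neck.midpoint)

    table = stage("build_tabletop_frame", build_tabletop_frame, landmarks,
                  cfg.scanner_axes, shaft=shaft)
    isb = stage("build_isb_frame", build_isb_frame, landmarks, head_center)

    plane, contour = stage("simulate_gt_cut", simulate_gt_cut, mesh,
                           landmarks.lateral_ridge_GT, shaft, table,
                           cut_offset_mm=cfg.cut_offset_mm,
                           thickness_mm=cfg.cap_thickness_mm,
                           tol_mm=cfg.thickness_tol_mm,
                           max_tilt_deg=cfg.max_tilt_deg)
    wall = stage("anterior_wall_line", anterior_wall_line, contour, isb,
                 cone_deg=cfg.wall_cone_deg, min_arc_mm=cfg.wall_min_arc_mm)

    head_ward = -n_axis.direction  # neck midpoint -> head centre (points medially)
    condylar_medial = unit(landmarks.medial_posterior_condyle
                           - landmarks.lateral_posterior_condyle)

    axial_normal = -shaft.direction if cfg.axial_view == "shaft" else table.proximal
    fa = stage("projected_angle(FA)", projected_angle, head_ward, condylar_medial,
               axial_normal, table.anterior)
    nsa = abs(stage("projected_angle(NSA)", projected_angle, head_ward, shaft.direction,
                    table.anterior, table.medial))
    # The wall line may lie very close to the sagittal view normal (the cut is
    # nearly transverse, and the tangent of an oblique wall to a transverse cut
    # runs mediolaterally).  Its projection is nevertheless well conditioned
    # whenever the wall is flat, because the line then lies in the wall plane,
    # which contains the view axis; hence the much smaller inclination guard.
    aw = stage("projected_angle(AW)", projected_angle, wall.line.direction, -shaft.direction,
               isb.lateral, isb.anterior, min_inclination_deg=0.02)
    wall_incl = float(np.degrees(np.arccos(np.clip(
        abs(np.dot(wall.line.direction, isb.lateral)), -1.0, 1.0))))

    diagnostics = {
        "sphere_rms_mm": sphere_rms,
        "head_radius_mm": head_radius,
        "neck_area_mm2": neck.area,
        "neck_iterations": neck.iterations,
        "neck_unique_minimum": neck.unique_minimum,
        "cut_tilt_deg": getattr(contour, "tilt_deg", np.nan),
        "cap_thickness_mm": getattr(contour, "cap_thickness_mm", np.nan),
        "wall_rms_mm": wall.rms_mm,
        "wall_arc_mm": wall.arc_length_mm,
        "wall_is_flat": wall.is_flat,
        "wall_line_inclination_deg": wall_incl,
    }
    # the axial view for FA is ambiguous between "perpendicular to the shaft"
    # and the table transverse plane; report the alternative as a diagnostic
    try:
        fa_table = projected_angle(head_ward, condylar_medial, table.proximal, table.anterior)
        diagnostics["fa_table_view_deg"] = fa_table
        diagnostics["fa_axial_vs_table_deg"] = fa - fa_table
    except GeometryError:
        pass

    if cfg.aw_sweep_offsets_mm:
        sweep = {}
        for off in cfg.aw_sweep_offsets_mm:
            try:
                _, c2 = simulate_gt_cut(mesh, landmarks.lateral_ridge_GT, shaft, table,
                                        cut_offset_mm=cfg.cut_offset_mm + off,
                                        thickness_mm=cfg.cap_thickness_mm,
                                        tol_mm=cfg.thickness_tol_mm,
                                        max_tilt_deg=cfg.max_tilt_deg)
                w2 = anterior_wall_line(c2, isb, cone_deg=cfg.wall_cone_deg,
                                        min_arc_mm=cfg.wall_min_arc_mm)
                sweep[off] = projected_angle(w2.line.direction, -shaft.direction,
                                             isb.lateral, isb.anterior)
            except MorphometryError as e:
                sweep[off] = str(e)
        diagnostics["aw_sweep_deg"] = sweep

    return AngleSet(fa=float(fa), nsa=float(nsa), aw=float(aw), side=isb.side,
                    diagnostics=diagnostics)
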