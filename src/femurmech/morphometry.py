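"""Automated 3D morphometry: landmark extraction and the 16 parameters.

The anatomical frame is built from the mesh itself: the femoral head
centre (FHC) from a least-squares sphere fit of the head surface, the
shaft axis (FSA) and neck axis (FNA) from iterative section fits, and
the three anatomical planes from the shaft axis and the condylar axis
(the frontal plane contains the FSA and is parallel to the condylar
axis; the transversal plane is perpendicular to the FSA).  Each of the
sixteen parameters is then evaluated in the plane its definition names:
angles from projected axis directions, lengths as (projected) point/line
or plane distances, the neck diameter as the minimal frontal-silhouette
width perpendicular to the projected neck axis.

Section fits use least-squares circles rather than raw point centroids
so that partially occluded rings (the neck emerging from the
intertrochanteric mass) still locate the section centre on the axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import FitConvergenceError, LandmarkError, SingularFitError
from .geometry import PART_HEAD, PART_NAMES, PART_NECK, PART_SHAFT, PART_TROCH
from .meshing import FemurModel
from .params import MorphologySet

__all__ = ["Line", "AnatomicalFrame", "fit_sphere", "fit_circle_2d",
           "fit_axis", "build_frame", "measure"]

#: separation of FSA and FNA beyond which FNAL is flagged as approximate
SKEW_WARN_MM = 10.0


@dataclass(frozen=True)
class Line:
    """A 3D line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def distance_to_point(self, p: np.ndarray) -> float:
        v = np.asarray(p) - self.point
        return float(np.linalg.norm(v - (v @ self.direction) * self.direction))

    def closest_points(self, other: "Line") -> Tuple[np.ndarray, np.ndarray]:
        """Closest points (on self, on other) between two lines."""
        u, v = self.direction, other.direction
        w = self.point - other.point
        uv = u @ v
        denom = 1.0 - uv * uv
        if denom < 1e-12:          # parallel: project other.point on self
            s = -(w @ u)
            return self.point + s * u, other.point
        s = (uv * (w @ v) - (w @ u)) / denom
        t = ((w @ v) - uv * (w @ u)) / denom
        return self.point + s * u, other.point + t * v


@dataclass(frozen=True)
class AnatomicalFrame:
    """Landmarks and planes of one femur.

    Plane normals are mutually orthogonal unit vectors; the transversal
    normal is the shaft-axis direction; ``frontal_normal`` points
    anterior and ``sagittal_normal`` points medial.
    """

    fhc: np.ndarray
    head_radius: float
    fsa: Line
    fna: Line
    frontal_normal: np.ndarray
    sagittal_normal: np.ndarray
    transversal_normal: np.ndarray
    condylar_axis: np.ndarray
    condylar_centre: np.ndarray
    gt_apex: np.ndarray
    lt_centre: np.ndarray


def fit_sphere(points: np.ndarray) -> Tuple[np.ndarray, float]:
    """Algebraic least-squares sphere through ``points``.

    Minimises Σ(‖p − c‖² − r²)², which is linear in (c, r² − ‖c‖²) and
    exact on noiseless spherical data.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise SingularFitError("sphere fit needs >= 4 points in 3D")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise SingularFitError("sphere fit is singular (coplanar points?)")
    centre = sol[:3]
    r_sq = sol[3] + centre @ centre
    if r_sq <= 0:
        raise SingularFitError("sphere fit produced non-positive radius")
    return centre, float(math.sqrt(r_sq))


def fit_circle_2d(xy: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares circle (Kåsa fit): returns (cx, cy, r)."""
    xy = np.asarray(xy, dtype=float)
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise SingularFitError("circle fit is singular (collinear points?)")
    cx, cy = sol[:2]
    r_sq = sol[2] + cx * cx + cy * cy
    return float(cx), float(cy), float(math.sqrt(max(r_sq, 0.0)))


def _plane_basis(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def fit_axis(points: np.ndarray, initial_direction: np.ndarray,
             n_stations: int = 12, station_span: Tuple[float, float] = (0.02, 0.98),
             min_station_points: int = 6, max_iter: int = 50,
             tol_deg: float = 0.01, section: str = "circle") -> Line:
    """Iterative axis fit of a tubular point cloud.

    Slices the cloud with planes perpendicular to the current axis
    estimate, locates each section centre (least-squares circle by
    default, centroid optionally), fits a total-least-squares line
    through the centres, and iterates until the direction changes by
    less than ``tol_deg``.
    """
    p = np.asarray(points, dtype=float)
    if len(p) == 0:
        raise LandmarkError("axis fit on an empty region")
    u = np.asarray(initial_direction, dtype=float)
    u = u / np.linalg.norm(u)
    history = []
    for it in range(max_iter):
        s = p @ u
        lo, hi = np.quantile(s, station_span)
        edges = np.linspace(lo, hi, n_stations + 1)
        e1, e2 = _plane_basis(u)
        centres = []
        weights = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (s >= a) & (s < b)
            if sel.sum() < min_station_points:
                continue
            q = p[sel]
            if section == "circle":
                cx, cy, _ = fit_circle_2d(np.column_stack([q @ e1, q @ e2]))
            else:
                cx, cy = float((q @ e1).mean()), float((q @ e2).mean())
            centres.append(cx * e1 + cy * e2 + float((q @ u).mean()) * u)
            weights.append(float(sel.sum()))
        if len(centres) < 5:
            raise LandmarkError(
                f"axis fit needs >= 5 populated sections, got {len(centres)}")
        c = np.asarray(centres)
        w = np.asarray(weights)
        w = w / w.sum()
        # point-count weighted total least squares through the centres:
        # sparsely populated (partially occluded) sections get less say
        mean = (c * w[:, None]).sum(axis=0)
        _, _, vt = np.linalg.svd((c - mean) * np.sqrt(w)[:, None],
                                 full_matrices=False)
        u_new = vt[0]
        if u_new @ u < 0:
            u_new = -u_new
        ang = math.degrees(math.acos(min(1.0, abs(u_new @ u))))
        if ang < tol_deg:
            return Line(point=mean, direction=u_new)
        history.append(u_new)
        # discrete station re-binning can trap the iteration in a small
        # limit cycle; once recent estimates stay within a tight cone,
        # accept their mean as the converged axis (the acceptable cone
        # widens as iterations accumulate; coarse surface sampling makes
        # the cycles larger but their mean remains accurate)
        if it >= 10:
            recent = np.asarray(history[-6:])
            mid = recent.mean(axis=0)
            mid /= np.linalg.norm(mid)
            spread = np.degrees(np.arccos(
                np.clip(np.abs(recent @ mid), -1.0, 1.0))).max()
            allowed = 0.5 if it < 20 else (1.0 if it < 35 else 2.0)
            if spread < allowed:
                return Line(point=mean, direction=mid)
        # damped update to suppress oscillation
        u = u + u_new
        u /= np.linalg.norm(u)
    raise FitConvergenceError(
        f"axis fit did not converge within {max_iter} iterations")


def _region_points(fm: FemurModel, tag: int) -> np.ndarray:
    idx = fm.surface_nodes(tag)
    if len(idx) == 0:
        raise LandmarkError(f"mesh has no tagged '{PART_NAMES[tag]}' region")
    return fm.nodes[idx]


def _shaft_band(fm: FemurModel, axis_dir: np.ndarray,
                band: Tuple[float, float]) -> np.ndarray:
    """Shaft surface points within a fractional station band of the length."""
    pts = _region_points(fm, PART_SHAFT)
    s_all = fm.nodes @ axis_dir
    smin, L = s_all.min(), s_all.max() - s_all.min()
    s = pts @ axis_dir
    sel = (s >= smin + band[0] * L) & (s <= smin + band[1] * L)
    return pts[sel]


def build_frame(fm: FemurModel) -> AnatomicalFrame:
    """Anatomical frame from the tagged surface of a femur mesh.

    The condylar axis and centre and the lesser-trochanter centre are
    analytic landmarks carried by the model (the distal epiphysis is not
    meshed in detail); everything else is fitted from the surface.
    """
    lm = fm.landmarks
    for key in ("condylar_axis", "condylar_centre", "lt_centre"):
        if key not in lm:
            raise LandmarkError(f"model landmark '{key}' is missing")

    # rough longitudinal direction from the node cloud
    nodes = fm.nodes
    mean = nodes.mean(axis=0)
    _, _, vt = np.linalg.svd(nodes[::7] - mean, full_matrices=False)
    u0 = vt[0]
    head_pts = _region_points(fm, PART_HEAD)
    if (head_pts.mean(axis=0) - mean) @ u0 < 0:
        u0 = -u0

    fsa = fit_axis(_shaft_band(fm, u0, (0.45, 0.75)), u0)
    u_s = fsa.direction if fsa.direction @ u0 > 0 else -fsa.direction
    fsa = Line(fsa.point, u_s)

    fhc, head_r = fit_sphere(head_pts)

    neck_pts = _region_points(fm, PART_NECK)
    foot = fsa.point + ((fhc - fsa.point) @ u_s) * u_s
    n0 = fhc - foot
    n0 /= np.linalg.norm(n0)
    fna = fit_axis(neck_pts, n0, n_stations=10, station_span=(0.10, 0.90))
    u_n = fna.direction if fna.direction @ n0 > 0 else -fna.direction
    fna = Line(fna.point, u_n)

    cond_axis = np.asarray(lm["condylar_axis"], dtype=float)
    cond_axis = cond_axis / np.linalg.norm(cond_axis)
    frontal = np.cross(u_s, cond_axis)
    nrm = np.linalg.norm(frontal)
    if nrm < 1e-9:
        raise LandmarkError("condylar axis is parallel to the shaft axis")
    frontal /= nrm
    sagittal = np.cross(frontal, u_s)
    sagittal /= np.linalg.norm(sagittal)

    troch_pts = _region_points(fm, PART_TROCH)
    gt_apex = troch_pts[np.argmax(troch_pts @ u_s)]

    return AnatomicalFrame(
        fhc=fhc, head_radius=head_r, fsa=fsa, fna=fna,
        frontal_normal=frontal, sagittal_normal=sagittal,
        transversal_normal=u_s, condylar_axis=cond_axis,
        condylar_centre=np.asarray(lm["condylar_centre"], dtype=float),
        gt_apex=gt_apex, lt_centre=np.asarray(lm["lt_centre"], dtype=float),
    )


def _proj(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - (v @ normal) * normal


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    c = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return math.degrees(math.acos(c))


def _neck_diameter(fm: FemurModel, frame: AnatomicalFrame) -> float:
    """Neck diameter: twice the minimal section radius along the FNA.

    For a circular neck this equals the minimal frontal-silhouette width
    perpendicular to the projected neck axis, but stays unbiased when
    part of a ring is hidden inside the intertrochanteric junction
    (least-squares circles recover the radius from partial arcs).
    """
    pts = _region_points(fm, PART_NECK)
    u = frame.fna.direction
    rel = pts - frame.fna.point
    s = rel @ u
    rho = np.linalg.norm(rel - s[:, None] * u, axis=1)
    i_min = int(np.argmin(rho))
    r_min = float(rho[i_min])
    s_star = s[i_min]
    # lower envelope per 1.5 mm station: the radial profile of the bare
    # neck; points lifted into junction fillets only ever sit above it
    bins = np.round((s - s_star) / 1.5).astype(int)
    env_s, env_r = [], []
    for b in np.unique(bins):
        sel = bins == b
        j = np.argmin(rho[sel])
        env_s.append(s[sel][j])
        env_r.append(rho[sel][j])
    s = np.asarray(env_s)
    rho = np.asarray(env_r)
    # the waist is a V of the distance-from-axis profile; the closest
    # sampled ring sits a little off the true minimum, so fit rho^2(s)
    # quadratics to both flanks (with a guard band so neither fit
    # straddles the kink) and intersect them
    right = (s >= s_star + 1.0) & (s <= s_star + 16.0)
    left = (s <= s_star - 1.0) & (s >= s_star - 10.0)
    if left.sum() < 5:        # stubby necks: widen towards the base
        left = (s <= s_star - 1.0) & (s >= s_star - 22.0)
    if left.sum() >= 5 and right.sum() >= 5:
        pl = np.polyfit(s[left], rho[left] ** 2, 2)
        pr = np.polyfit(s[right], rho[right] ** 2, 2)
        roots = np.roots(np.asarray(pl) - np.asarray(pr))
        roots = roots[np.isreal(roots)].real
        roots = roots[np.abs(roots - s_star) <= 5.0]
        if len(roots):
            s_x = roots[np.argmin(np.abs(roots - s_star))]
            val = min(np.polyval(pl, s_x), np.polyval(pr, s_x))
            if val > 0:
                r_v = float(np.sqrt(val))
                if 0.7 * r_min <= r_v <= r_min:
                    r_min = r_v
    return float(2.0 * r_min)


def measure(fm: FemurModel, frame: Optional[AnatomicalFrame] = None
            ) -> MorphologySet:
    """Compute all sixteen morphological parameters of a femur mesh."""
    if frame is None:
        frame = build_frame(fm)
    u_s = frame.transversal_normal
    f_n = frame.frontal_normal
    s_n = frame.sagittal_normal
    u_n = frame.fna.direction
    fhc = frame.fhc

    # angles
    nsa = _angle_deg(_proj(u_n, f_n), _proj(-u_s, f_n))
    pn = _proj(u_n, u_s)
    ata = math.degrees(math.atan2(pn @ f_n, pn @ s_n))
    mech = fhc - frame.condylar_centre
    amsa = _angle_deg(_proj(mech, f_n), _proj(u_s, f_n))
    dist_dir = fit_axis(_shaft_band(fm, u_s, (0.08, 0.30)), u_s).direction
    prox_dir = fit_axis(_shaft_band(fm, u_s, (0.45, 0.75)), u_s).direction
    ba = _angle_deg(_proj(dist_dir, s_n), _proj(prox_dir, s_n))

    # neck axis intersection and head offsets
    p_fsa, p_fna = frame.fsa.closest_points(frame.fna)
    if np.linalg.norm(p_fsa - p_fna) > SKEW_WARN_MM:
        warnings.warn(
            "FSA and FNA are strongly skew; FNAL uses the closest-approach "
            "point on the FNA", stacklevel=2)
    fnal = float(np.linalg.norm(fhc - p_fna))
    q = frame.fna.point + ((fhc - frame.fna.point) @ u_n) * u_n
    dvec = fhc - q
    dchd = float(dvec @ f_n)
    dcvd = float(dvec @ u_s)
    ncdf = float(np.linalg.norm(_proj(dvec, f_n)))
    ncds = float(np.linalg.norm(_proj(dvec, s_n)))

    # shaft-axis offsets
    osa = frame.fsa.distance_to_point(fhc)
    v = fhc - frame.fsa.point
    v_f = _proj(v, f_n)
    u_f = _proj(u_s, f_n)
    u_f /= np.linalg.norm(u_f)
    osh = float(np.linalg.norm(v_f - (v_f @ u_f) * u_f))

    # axial (vertical) distances
    gth = float((fhc - frame.gt_apex) @ u_s)
    osv = float((fhc - frame.lt_centre) @ u_s)
    s_all = fm.nodes @ u_s
    tfl = float(s_all.max() - s_all.min())

    return MorphologySet(
        ATA=ata, aMSA=amsa, BA=ba, DCHD=dchd, DCVD=dcvd,
        FHD=2.0 * frame.head_radius, FNAL=fnal, GTH=gth,
        NCDF=ncdf, NCDS=ncds, ND=_neck_diameter(fm, frame), NSA=nsa,
        OSA=osa, OSH=osh, OSV=osv, TFL=tfl,
    )
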