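"""Parametric construction of a femur solid from a morphology set.

The solid is the union of four analytic parts, expressed in a canonical
right-femur frame (x lateral→medial, y posterior→anterior, z distal→
proximal, neck-shaft intersection at the origin):

* **shaft** — a tube along the femoral shaft axis, bent in the sagittal
  plane by ``BA`` at 35 % of the femur length, with a distal (condylar)
  and proximal (metaphyseal) flare;
* **neck** — a surface of revolution about the neck axis whose waist
  diameter is ``ND`` and which flares (two concave elliptic bulges) to
  swallow the back of the head sphere (junction at 60° polar angle) and
  to merge into the intertrochanteric region at its base;
* **head** — a sphere of diameter ``FHD`` centred at the head centre
  ``FHC = FNAL·n + d`` where ``d`` is the small perpendicular offset
  encoded by ``DCHD``/``DCVD``;
* **greater trochanter** — an ellipsoid whose apex realises ``GTH`` and
  protrudes a few millimetres laterally of the remaining silhouette.

Cross-sections perpendicular to the shaft axis are star-shaped around a
continuous centre curve ``c(z)``; the outer boundary is obtained by
ray-casting against all parts and merging the resulting intervals
(radial gaps below ``merge_gap`` are bridged, which fills narrow
junction crevices the way cortical fillets do on real bone).  The
surface radius field is finally smoothed with a Lipschitz bound along z
so that the swept mesh cannot fold over at part transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ConstructionError
from .params import (
    GeneratorConfig,
    MorphologySet,
    head_centre_offset,
    neck_axis_direction,
)

__all__ = ["ParametricFemur", "PART_NONE", "PART_SHAFT", "PART_TROCH",
           "PART_NECK", "PART_HEAD", "PART_DISTAL", "PART_NAMES"]

# surface part tags
PART_NONE = 0      # junction fillet / draped transition
PART_SHAFT = 1
PART_TROCH = 2
PART_NECK = 3
PART_HEAD = 4
PART_DISTAL = 5    # distal cut disk

PART_NAMES = {PART_NONE: "junction", PART_SHAFT: "shaft", PART_TROCH: "trochanter",
              PART_NECK: "neck", PART_HEAD: "head", PART_DISTAL: "condyles"}

_MID_SHAFT_RADIUS = 13.5     # mm, outer radius of the diaphysis
_META_RADIUS = 17.0          # mm, proximal metaphyseal radius
_DISTAL_FLARE_RADIUS = 22.0  # mm, radius at the distal (condylar) cut
_DISTAL_FLARE_LEN = 45.0     # mm
_NECK_BASE_RADIUS = 25.0     # mm, hyperboloid radius at the shaft axis
_BEND_FRACTION = 0.35        # sagittal bend position, fraction of TFL from distal
_BEND_HALFWIDTH = 15.0       # mm, smoothing half-width of the bend
_HEAD_JUNCTION_ANGLE = 60.0  # deg, polar angle of the neck-head junction circle
_TROCH_AX, _TROCH_AY, _TROCH_AZ = 16.0, 13.0, 12.0   # trochanter semi-axes, mm
_TROCH_PROTRUSION = 5.0      # mm, lateral protrusion of the apex
_DRAPE_SLOPE = 3.0           # max |dR/dz| enforced on the swept radius field


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class ParametricFemur:
    """Analytic femur solid for one morphology set.

    Provides the cross-section boundary ``R(θ, z)`` (with part tags), the
    centre curve, the cortical thickness target per part, and the
    ground-truth anatomical landmarks.
    """

    morphology: MorphologySet
    config: GeneratorConfig

    # derived quantities, filled in __post_init__
    neck_dir: np.ndarray = field(init=False)
    head_offset: np.ndarray = field(init=False)
    fhc: np.ndarray = field(init=False)
    head_radius: float = field(init=False)
    z_top: float = field(init=False)
    z_end: float = field(init=False)
    z_cut: float = field(init=False)
    z_apex: float = field(init=False)
    z_lt: float = field(init=False)
    z_bend: float = field(init=False)
    z_shaft_top: float = field(init=False)
    condylar_centre: np.ndarray = field(init=False)
    condylar_axis: np.ndarray = field(init=False)
    lt_centre: np.ndarray = field(init=False)
    gt_apex: np.ndarray = field(init=False)
    troch_centre: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = self.morphology
        self.neck_dir = neck_axis_direction(m.NSA, m.ATA)
        self.head_offset = head_centre_offset(m.as_dict())
        self.fhc = m.FNAL * self.neck_dir + self.head_offset
        self.head_radius = m.FHD / 2.0
        self.z_top = self.fhc[2] + self.head_radius
        self.z_end = self.z_top - m.TFL
        self.z_cut = self.z_top - 2.0 * m.TFL / 3.0
        self.z_apex = self.fhc[2] - m.GTH
        self.z_lt = self.fhc[2] - m.OSV
        self.z_bend = self.z_end + _BEND_FRACTION * m.TFL
        self.z_shaft_top = 10.0

        # neck of revolution, waist radius ND/2 at s_w, flaring both ways:
        #   base piece  (s in [s_b, s_w]): r^2 = rb^2  - kb (s - s_b)^2
        #   head piece  (s in [s_w, s_j]): r^2 = rho^2 - kh (s - s_j)^2
        # both concave in s so that horizontal ray intersections stay
        # positive-definite quadratics.
        self._r_w = m.ND / 2.0
        self._s_j = m.FNAL - self.head_radius * math.cos(
            math.radians(_HEAD_JUNCTION_ANGLE))
        self._s_b = -8.0
        # keep the waist distal of where the head sphere covers the neck,
        # otherwise the sampled ND would never appear on the surface
        s_cover = m.FNAL - math.sqrt(max(
            self.head_radius ** 2 - self._r_w ** 2, 0.0))
        self._s_w = min(0.5 * m.FNAL, s_cover - 2.5)
        if self._s_w < 5.0:
            raise ConstructionError(
                "neck waist cannot be exposed between head and shaft "
                f"(FNAL={m.FNAL:.1f}, FHD={m.FHD:.1f}, ND={m.ND:.1f})")
        if self._s_j - self._s_w < 3.0:
            raise ConstructionError(
                "head sphere not attachable to neck: junction station "
                f"{self._s_j:.1f} too close to waist {self._s_w:.1f} "
                "(FNAL too short for FHD)")
        self._r_b = max(_NECK_BASE_RADIUS, self._r_w + 1.0)
        self._k_b = (self._r_b ** 2 - self._r_w ** 2) / (
            self._s_w - self._s_b) ** 2
        self._rho_j, self._k_h = self._head_side_flare()

        # trochanter ellipsoid, apex protruding laterally of the silhouette
        x_lat = self._lateral_extent(self.z_apex)
        cx, cy = self.centre(np.array([self.z_apex]))
        self.troch_centre = np.array(
            [x_lat - _TROCH_PROTRUSION, float(cy[0]),
             self.z_apex - _TROCH_AZ])
        self.gt_apex = np.array(
            [self.troch_centre[0], self.troch_centre[1], self.z_apex])

        # distal landmarks (analytic; the mechanics uses only the proximal 2/3)
        x_cc = self.fhc[0] - math.tan(math.radians(m.aMSA)) * (
            self.fhc[2] - self.z_end)
        self.condylar_centre = np.array(
            [x_cc, float(self.shaft_centre_y(np.array([self.z_end]))[0]),
             self.z_end])
        self.condylar_axis = np.array([1.0, 0.0, 0.0])

        # lesser trochanter landmark on the posteromedial surface
        theta = np.array([-math.pi / 4.0])
        r, _ = self.cross_section(self.z_lt, theta)
        cx, cy = self.centre(np.array([self.z_lt]))
        self.lt_centre = np.array(
            [float(cx[0] + r[0] * math.cos(theta[0])),
             float(cy[0] + r[0] * math.sin(theta[0])), self.z_lt])
        if not np.isfinite(r[0]) or r[0] <= 0:
            raise ConstructionError("lesser-trochanter level has empty section")

    # ------------------------------------------------------------------ parts

    def _head_side_flare(self) -> Tuple[float, float]:
        """Junction radius and curvature so the neck swallows the head back.

        The head-side piece must stay above the sphere's distance-from-axis
        profile so that the union surface transitions from neck to head at
        the junction circle without an overhang.
        """
        m = self.morphology
        d_norm = float(np.linalg.norm(self.head_offset))
        s = np.linspace(max(self._s_w + 1.0, m.FNAL - self.head_radius + 0.2),
                        self._s_j - 1e-6, 60)
        need = np.sqrt(np.maximum(
            self.head_radius ** 2 - (m.FNAL - s) ** 2, 0.0)) + d_norm + 0.8
        rho = self.head_radius * math.sin(
            math.radians(_HEAD_JUNCTION_ANGLE)) + d_norm + 0.8
        for _ in range(40):
            k = (rho ** 2 - self._r_w ** 2) / (self._s_j - self._s_w) ** 2
            r_sq = rho ** 2 - k * (s - self._s_j) ** 2
            if np.all(r_sq >= need ** 2 - 1e-9):
                return float(rho), float(k)
            rho += 0.25
        raise ConstructionError(
            "cannot flare neck to enclose the head sphere "
            f"(FNAL={m.FNAL:.1f}, FHD={m.FHD:.1f}, ND={m.ND:.1f})")

    def shaft_centre_y(self, z: np.ndarray) -> np.ndarray:
        """Sagittal bow of the shaft centreline (posterior deflection)."""
        u = self.z_bend - z
        w = _BEND_HALFWIDTH
        g = np.where(u <= -w, 0.0,
                     np.where(u >= w, u, (u + w) ** 2 / (4.0 * w)))
        return -math.tan(math.radians(self.morphology.BA)) * g

    def shaft_radius(self, z: np.ndarray) -> np.ndarray:
        r = np.full_like(z, _MID_SHAFT_RADIUS, dtype=float)
        r += (_DISTAL_FLARE_RADIUS - _MID_SHAFT_RADIUS) * _smoothstep(
            (self.z_end + _DISTAL_FLARE_LEN - z) / _DISTAL_FLARE_LEN)
        r += (_META_RADIUS - _MID_SHAFT_RADIUS) * _smoothstep((z + 25.0) / 30.0)
        return r

    def neck_radius_sq(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        base = self._r_b ** 2 - self._k_b * (s - self._s_b) ** 2
        head = self._rho_j ** 2 - self._k_h * (s - self._s_j) ** 2
        return np.where(s < self._s_w, base, head)

    def centre(self, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Continuous star-centre curve of the cross-sections."""
        n = self.neck_dir
        zc = np.clip(z, 0.0, self.fhc[2])
        xn = n[0] / n[2] * zc
        yn = n[1] / n[2] * zc
        w = _smoothstep(z / max(self.fhc[2], 1.0))
        cx = w * xn
        cy = (1.0 - w) * self.shaft_centre_y(z) + w * yn
        # converge to the exact head centre over the upper head so the
        # shrinking top sections always contain the star centre
        wh = _smoothstep((z - self.fhc[2] + 0.5 * self.head_radius)
                         / (0.75 * self.head_radius))
        cx = (1.0 - wh) * cx + wh * self.fhc[0]
        cy = (1.0 - wh) * cy + wh * self.fhc[1]
        return cx, cy

    # ------------------------------------------------------- ray intersections

    @staticmethod
    def _quad_interval(A, B, C):
        """Solve A t^2 + B t + C <= 0; returns (t1, t2) or NaNs."""
        disc = B * B - 4.0 * A * C
        ok = (disc > 0.0) & (A > 1e-12)
        sq = np.sqrt(np.maximum(disc, 0.0))
        t1 = np.where(ok, (-B - sq) / (2.0 * A), np.nan)
        t2 = np.where(ok, (-B + sq) / (2.0 * A), np.nan)
        return t1, t2

    def _shaft_interval(self, z, cx, cy, ux, uy):
        if not (self.z_end - 1e-4 <= z <= self.z_shaft_top):
            return None
        ox = cx - 0.0
        oy = cy - float(self.shaft_centre_y(np.array([z]))[0])
        r = float(self.shaft_radius(np.array([z]))[0])
        A = ux * ux + uy * uy
        B = 2.0 * (ox * ux + oy * uy)
        C = ox * ox + oy * oy - r * r
        return self._quad_interval(A, B, C)

    def _head_interval(self, z, cx, cy, ux, uy):
        dz = z - self.fhc[2]
        rr = self.head_radius ** 2 - dz * dz
        if rr <= 0.0:
            return None
        ox = cx - self.fhc[0]
        oy = cy - self.fhc[1]
        A = ux * ux + uy * uy
        B = 2.0 * (ox * ux + oy * uy)
        C = ox * ox + oy * oy - rr
        return self._quad_interval(A, B, C)

    def _troch_interval(self, z, cx, cy, ux, uy):
        tc = self.troch_centre
        k = 1.0 - ((z - tc[2]) / _TROCH_AZ) ** 2
        if k <= 0.0:
            return None
        ax2 = (_TROCH_AX ** 2) * k
        ay2 = (_TROCH_AY ** 2) * k
        ox = cx - tc[0]
        oy = cy - tc[1]
        A = ux * ux / ax2 + uy * uy / ay2
        B = 2.0 * (ox * ux / ax2 + oy * uy / ay2)
        C = ox * ox / ax2 + oy * oy / ay2 - 1.0
        return self._quad_interval(A, B, C)

    def _neck_interval(self, z, cx, cy, ux, uy):
        """Hyperboloid about the neck axis, clipped to s in [s_lo, s_j].

        Solved piecewise (base / head side of the waist) and unioned; the
        two pieces agree at the waist so the union is contiguous.
        """
        n = self.neck_dir
        # q(t) = (cx + t ux, cy + t uy, z); w = q; s = w . n
        s0 = cx * n[0] + cy * n[1] + z * n[2]
        su = ux * n[0] + uy * n[1]
        w2_0 = cx * cx + cy * cy + z * z
        w2_1 = 2.0 * (cx * ux + cy * uy)
        w2_2 = ux * ux + uy * uy
        out = []
        for r0_sq, k, s_ref, s_min, s_max in (
            (self._r_b ** 2, self._k_b, self._s_b, self._s_b, self._s_w),
            (self._rho_j ** 2, self._k_h, self._s_j, self._s_w, self._s_j),
        ):
            # rho^2 - r^2(s) = w2 - s^2 - r0^2 + k (s - s_ref)^2 <= 0
            A = w2_2 - su * su + k * su * su
            B = w2_1 - 2.0 * s0 * su + 2.0 * k * su * (s0 - s_ref)
            C = w2_0 - s0 * s0 - r0_sq + k * (s0 - s_ref) ** 2
            t1, t2 = self._quad_interval(np.asarray(A), np.asarray(B),
                                         np.asarray(C))
            # clip to the s-range of this piece along the ray
            su_a = np.broadcast_to(np.asarray(su, dtype=float), t1.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                ta = (s_min - s0) / su_a
                tb = (s_max - s0) / su_a
            lo = np.where(su_a > 0, ta, tb)
            hi = np.where(su_a > 0, tb, ta)
            par = np.abs(su_a) <= 1e-12      # ray parallel to waist planes
            in_rng = (s_min <= s0) & (s0 <= s_max)
            lo = np.where(par, np.where(in_rng, -np.inf, np.inf), lo)
            hi = np.where(par, np.where(in_rng, np.inf, -np.inf), hi)
            t1 = np.maximum(t1, lo)
            surf = t2 < hi - 1e-9      # outer hit on the quadric, not a clip plane
            t2 = np.minimum(t2, hi)
            good = np.asarray(t1) < np.asarray(t2)
            t1 = np.where(good, t1, np.nan)
            t2 = np.where(good, t2, np.nan)
            out.append((t1, t2, surf & good))
        if not out:
            return None
        if len(out) == 1:
            return out[0]
        # union of the two contiguous pieces; keep the flag of the outer one
        t1 = np.fmin(out[0][0], out[1][0])
        second = np.fmax(out[1][1], -np.inf) >= np.fmax(out[0][1], -np.inf)
        t2 = np.fmax(out[0][1], out[1][1])
        surf = np.where(second, out[1][2], out[0][2])
        return t1, t2, surf

    def _lateral_extent(self, z: float) -> float:
        """Leftmost (most lateral) x of the silhouette, trochanter excluded."""
        theta = np.array([math.pi])
        r, _ = self.cross_section(z, theta, include_troch=False)
        cx, _ = self.centre(np.array([z]))
        if not np.isfinite(r[0]):
            raise ConstructionError(
                f"empty cross-section at trochanter apex height z={z:.1f}")
        return float(cx[0] - r[0])

    # ------------------------------------------------------------ public API

    def cross_section(self, z: float, theta: np.ndarray,
                      include_troch: bool = True
                      ) -> Tuple[np.ndarray, np.ndarray]:
        """Boundary radius and part tag for rays at ``theta`` from c(z)."""
        cx_a, cy_a = self.centre(np.array([float(z)]))
        cx, cy = float(cx_a[0]), float(cy_a[0])
        ux, uy = np.cos(theta), np.sin(theta)
        parts = []
        tags = []
        for tag, fn in ((PART_SHAFT, self._shaft_interval),
                        (PART_TROCH, self._troch_interval),
                        (PART_NECK, self._neck_interval),
                        (PART_HEAD, self._head_interval)):
            if tag == PART_TROCH and not include_troch:
                continue
            iv = fn(float(z), cx, cy, ux, uy)
            if iv is not None:
                parts.append(iv)
                tags.append(tag)
        R = np.full(theta.shape, np.nan)
        best = np.zeros(theta.shape, dtype=np.int8)
        if not parts:
            return R, best
        t1s = np.stack([np.broadcast_to(p[0], theta.shape) for p in parts])
        t2s = np.stack([np.broadcast_to(p[1], theta.shape) for p in parts])
        surfs = np.stack([
            np.broadcast_to(p[2], theta.shape) if len(p) == 3
            else np.ones(theta.shape, dtype=bool) for p in parts])
        tag_arr = np.array(tags, dtype=np.int8)
        gap = self.config.merge_gap
        # merge intervals into the component containing t = 0
        order = np.argsort(np.where(np.isnan(t1s), np.inf, t1s), axis=0)
        npart = len(parts)
        Rcur = np.full(theta.shape, -np.inf)
        inside = np.zeros(theta.shape, dtype=bool)
        for rank in range(npart):
            idx = order[rank]
            sel = np.take_along_axis(t1s, idx[None], axis=0)[0]
            sel2 = np.take_along_axis(t2s, idx[None], axis=0)[0]
            ssurf = np.take_along_axis(surfs, idx[None], axis=0)[0]
            stag = np.where(ssurf, tag_arr[idx], PART_NONE)
            valid = np.isfinite(sel) & np.isfinite(sel2)
            start = valid & (sel <= 0.0) & (sel2 >= 0.0)
            grow = valid & inside & (sel <= Rcur + gap) & (sel2 > Rcur)
            take = start | grow
            newR = np.where(take, np.maximum(Rcur, sel2), Rcur)
            best = np.where(take & (newR > Rcur), stag, best)
            Rcur = newR
            inside = inside | start
        R = np.where(inside, Rcur, np.nan)
        best = np.where(inside, best, 0).astype(np.int8)
        return R, best

    def thickness_for_tag(self, tag: np.ndarray) -> np.ndarray:
        """Target cortical thickness (mm) per surface part tag."""
        th = self.config.cortical_thickness
        scale = self.config.thickness_scale
        table = np.array([
            th["trochanter"],    # junction fillets: intertrochanteric crest
            th["shaft"], th["trochanter"], th["neck"], th["head"],
            th["shaft"],
        ]) * scale
        return table[np.clip(tag, 0, 5)]

    def landmarks(self) -> Dict[str, np.ndarray]:
        return {
            "fhc": self.fhc.copy(),
            "shaft_axis_point": np.zeros(3),
            "shaft_axis_dir": np.array([0.0, 0.0, 1.0]),
            "neck_axis_point": np.zeros(3),
            "neck_axis_dir": self.neck_dir.copy(),
            "condylar_axis": self.condylar_axis.copy(),
            "condylar_centre": self.condylar_centre.copy(),
            "gt_apex": self.gt_apex.copy(),
            "lt_centre": self.lt_centre.copy(),
        }
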