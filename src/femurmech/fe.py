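"""Quasi-static linear-elastic finite elements for the femur load cases.

Two load cases are modelled, both applying a compressive force through a
reference point rigidly coupled to a 10 mm spherical cap of the femoral
head, with the distal third of the (trimmed) femur fully fixed:

* **stumbling** — single-leg-stance-like: the load axis makes 8° with
  the shaft axis in the frontal plane;
* **lateral fall** — the load axis makes 10° with the shaft axis and its
  transversal projection makes the femur's own antetorsion angle with
  the condylar (mediolateral) axis; the greater-trochanter patch is
  additionally supported along the load axis.

Bone is homogeneous, isotropic and linear elastic per region (cortical
16 GPa, trabecular 0.5 GPa, ν = 0.3).  The system is reduced by exact
constraint elimination (fixed nodes dropped, cap nodes condensed into
six rigid-body dofs of the reference point, trochanter nodes rotated
into a local basis with the load-axis component removed) and solved
with a banded Cholesky factorisation plus a small Schur complement for
the reference dofs.  Strains scale linearly with load, so a single
solve at the 100 N reference load determines the whole load ramp.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    AssemblyError,
    ConfigurationError,
    PatchSelectionError,
    RigidBodyModeError,
)
from .geometry import PART_HEAD
from .meshing import REGION_CORTICAL, FemurModel
from .morphometry import AnatomicalFrame, Line

__all__ = [
    "MaterialAndCriterionConfig", "LoadCaseModel", "ElementStrainField",
    "configure_load_case", "assemble_and_solve", "frame_from_landmarks",
    "face_adjacency",
]

CASE_STUMBLING = "stumbling"
CASE_FALL = "lateral_fall"

_STANCE_TILT_DEG = 8.0     # load axis vs shaft axis, frontal plane
_FALL_TILT_DEG = 10.0      # load axis vs shaft axis (shaft 10° off vertical)
_CAP_HEIGHT_MM = 10.0      # height of the loaded head cap
_TROCH_PATCH_RADIUS = 18.0 # outer radius of the trochanter support patch
_TROCH_PATCH_CORE = 9.0    # full-stiffness core radius (cosine taper beyond)


@dataclass(frozen=True)
class MaterialAndCriterionConfig:
    """Material constants, load programme and failure-criterion limits.

    Units: MPa (N/mm²), N, mm, dimensionless strain.
    """

    E_cortical: float = 16000.0
    E_trabecular: float = 500.0
    poisson: float = 0.3
    eps_tensile: float = 0.0073
    eps_compressive: float = 0.0104
    V_crit: float = 100.0
    dF: float = 100.0
    F_max: float = 10000.0
    F_ref: float = 100.0
    embedding_depth: float = 70.0
    E_embedding: float = 2400.0
    nu_embedding: float = 0.35
    #: trochanter support: "foundation" presses the patch against an
    #: elastic layer of the embedding polymer acting along the load axis;
    #: "rigid" constrains the patch displacement along the load axis to zero
    troch_support: str = "foundation"
    #: effective thickness (mm) of the polymer layer under the trochanter
    troch_foundation_thickness: float = 24.0

    def validate(self) -> None:
        for name in ("E_cortical", "E_trabecular", "eps_tensile",
                     "eps_compressive", "V_crit", "dF", "F_max", "F_ref"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not 0 <= self.poisson < 0.5:
            raise ConfigurationError("poisson must lie in [0, 0.5)")
        n = self.F_max / self.dF
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("dF must divide F_max")
        if self.troch_support not in ("foundation", "rigid"):
            raise ConfigurationError(
                "troch_support must be 'foundation' or 'rigid'")


@dataclass
class LoadCaseModel:
    """A trimmed femur with boundary conditions for one load case."""

    model: FemurModel
    case: str
    config: MaterialAndCriterionConfig
    load_axis: np.ndarray
    reference_point: np.ndarray
    fixed_nodes: np.ndarray
    cap_nodes: np.ndarray
    troch_nodes: np.ndarray          # empty for stumbling
    frame: AnatomicalFrame


@dataclass
class ElementStrainField:
    """Per-element principal strains at the reference load.

    ``e_max`` / ``e_min`` are the maximum / minimum principal strains of
    each element at ``F_ref``; strains at any other load follow by
    linear scaling.  ``adjacency`` lists face-adjacent element pairs.
    """

    e_max: np.ndarray
    e_min: np.ndarray
    volume: np.ndarray
    region: np.ndarray
    adjacency: np.ndarray
    F_ref: float
    case: str
    diagnostics: Dict[str, float] = field(default_factory=dict)

    def at_load(self, F: float) -> Tuple[np.ndarray, np.ndarray]:
        s = F / self.F_ref
        return self.e_max * s, self.e_min * s


def face_adjacency(tets: np.ndarray) -> np.ndarray:
    """Pairs of elements sharing a triangular face, shape (m, 2)."""
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    owner = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key = key[order]
    owner = owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    return np.stack([owner[:-1][same], owner[1:][same]], axis=1)


def frame_from_landmarks(fm: FemurModel) -> AnatomicalFrame:
    """Anatomical frame straight from the generator landmarks.

    Convenience for mechanics-only runs; cohort pipelines use the frame
    measured by the morphometry module instead.
    """
    lm = fm.landmarks
    u_s = np.asarray(lm["shaft_axis_dir"], dtype=float)
    u_s = u_s / np.linalg.norm(u_s)
    cond = np.asarray(lm["condylar_axis"], dtype=float)
    cond = cond / np.linalg.norm(cond)
    frontal = np.cross(u_s, cond)
    frontal /= np.linalg.norm(frontal)
    sagittal = np.cross(frontal, u_s)
    fhc = np.asarray(lm["fhc"], dtype=float)
    gt = fm.ground_truth
    head_r = gt.FHD / 2.0 if gt is not None else float(
        np.linalg.norm(fm.nodes[fm.surface_nodes(PART_HEAD)] - fhc, axis=1).mean())
    return AnatomicalFrame(
        fhc=fhc, head_radius=head_r,
        fsa=Line(np.asarray(lm["shaft_axis_point"], dtype=float), u_s),
        fna=Line(np.asarray(lm["neck_axis_point"], dtype=float),
                 np.asarray(lm["neck_axis_dir"], dtype=float)),
        frontal_normal=frontal, sagittal_normal=sagittal,
        transversal_normal=u_s, condylar_axis=cond,
        condylar_centre=np.asarray(lm["condylar_centre"], dtype=float),
        gt_apex=np.asarray(lm["gt_apex"], dtype=float),
        lt_centre=np.asarray(lm["lt_centre"], dtype=float),
    )


def load_axis_for_case(case: str, frame: AnatomicalFrame,
                       ata_deg: Optional[float] = None) -> np.ndarray:
    """Unit load direction (pointing distally, i.e. compressive)."""
    u_s = frame.transversal_normal
    s_n = frame.sagittal_normal
    f_n = frame.frontal_normal
    if case == CASE_STUMBLING:
        t = math.radians(_STANCE_TILT_DEG)
        axis = -math.cos(t) * u_s - math.sin(t) * s_n
    elif case == CASE_FALL:
        if ata_deg is None:
            pn = frame.fna.direction - (frame.fna.direction @ u_s) * u_s
            ata_deg = math.degrees(math.atan2(pn @ f_n, pn @ s_n))
        # the femur is adducted 10° from the vertical load axis, so in the
        # bone frame the load tilts medially; its transversal projection
        # makes the native antetorsion angle with the mediolateral axis
        t = math.radians(_FALL_TILT_DEG)
        a = math.radians(ata_deg)
        axis = (-math.cos(t) * u_s
                + math.sin(t) * (math.cos(a) * s_n + math.sin(a) * f_n))
    else:
        raise ConfigurationError(f"unknown load case {case!r}")
    return axis / np.linalg.norm(axis)


def configure_load_case(fm: FemurModel, case: str,
                        cfg: Optional[MaterialAndCriterionConfig] = None,
                        frame: Optional[AnatomicalFrame] = None,
                        ata_deg: Optional[float] = None) -> LoadCaseModel:
    """Attach boundary conditions for one load case to a trimmed femur."""
    cfg = cfg or MaterialAndCriterionConfig()
    cfg.validate()
    if not fm.trimmed or fm.embedded_nodes is None:
        raise ConfigurationError(
            "load cases require a trimmed femur with an embedded node set "
            "(run trim_and_embed first)")
    if frame is None:
        frame = frame_from_landmarks(fm)
    axis = load_axis_for_case(case, frame, ata_deg)

    surf = fm.surface_nodes()
    head = surf[fm.node_tags[surf] == PART_HEAD]
    rel = fm.nodes[head] - frame.fhc
    cap = head[rel @ (-axis) >= frame.head_radius - _CAP_HEIGHT_MM]
    if len(cap) == 0:
        raise PatchSelectionError("loading cap on the femoral head is empty")

    fixed = np.asarray(fm.embedded_nodes)
    if case == CASE_FALL:
        # support patch = surface faces whose centroid lies within the
        # patch radius of the apex (face-based selection keeps the patch
        # area mesh-independent)
        fc = fm.nodes[fm.surface_faces].mean(axis=1)
        d = np.linalg.norm(fc - frame.gt_apex, axis=1)
        faces = fm.surface_faces[d <= _TROCH_PATCH_RADIUS]
        troch = np.setdiff1d(np.unique(faces), cap)
        if len(troch) == 0:
            raise PatchSelectionError("trochanter support patch is empty")
    else:
        troch = np.empty(0, dtype=np.int64)
    cap = np.setdiff1d(cap, fixed)
    troch = np.setdiff1d(troch, fixed)

    return LoadCaseModel(
        model=fm, case=case, config=cfg, load_axis=axis,
        reference_point=np.asarray(frame.fhc, dtype=float),
        fixed_nodes=fixed, cap_nodes=cap, troch_nodes=troch, frame=frame,
    )


# ------------------------------------------------------------------ elements

_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]


def _elastic_d(E: np.ndarray, nu: float) -> np.ndarray:
    """Isotropic elasticity matrices (ne, 6, 6), engineering shear."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


def _tet_gradients(nodes: np.ndarray, tets: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (ne, 4, 3) and volumes of linear tets."""
    X = nodes[tets]
    J = X[:, 1:] - X[:, :1]
    vol = np.linalg.det(J) / 6.0
    if np.any(vol <= 0):
        raise AssemblyError("mesh contains non-positively oriented tets")
    Jinv = np.linalg.inv(J)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = Jinv.transpose(0, 2, 1)
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol


def _b_matrix(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (ne, 6, 3*nn) from gradients (ne, nn, 3)."""
    ne, nn, _ = g.shape
    B = np.zeros((ne, 6, 3 * nn))
    for a in range(nn):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        B[:, 0, 3 * a + 0] = gx
        B[:, 1, 3 * a + 1] = gy
        B[:, 2, 3 * a + 2] = gz
        B[:, 3, 3 * a + 0] = gy
        B[:, 3, 3 * a + 1] = gx
        B[:, 4, 3 * a + 1] = gz
        B[:, 4, 3 * a + 2] = gy
        B[:, 5, 3 * a + 0] = gz
        B[:, 5, 3 * a + 2] = gx
    return B


def _quadratic_connectivity(nodes: np.ndarray, tets: np.ndarray
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Midside nodes for 10-node tets; returns (all_nodes, conn10)."""
    edges = tets[:, [[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]]]
    flat = np.sort(edges.reshape(-1, 2), axis=1)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    conn = np.concatenate(
        [tets, len(nodes) + inv.reshape(len(tets), 6)], axis=1)
    return np.concatenate([nodes, mid]), conn


# 4-point Gauss rule for tets (degree 2)
_GP_A, _GP_B = (5.0 + 3.0 * math.sqrt(5.0)) / 20.0, (5.0 - math.sqrt(5.0)) / 20.0
_GAUSS_TET4 = np.array([
    [_GP_A, _GP_B, _GP_B, _GP_B],
    [_GP_B, _GP_A, _GP_B, _GP_B],
    [_GP_B, _GP_B, _GP_A, _GP_B],
    [_GP_B, _GP_B, _GP_B, _GP_A],
])


def _tet10_shape_gradients(bary: np.ndarray) -> np.ndarray:
    """d N / d (λ1..λ4) for the 10-node tet at one barycentric point."""
    l1, l2, l3, l4 = bary
    dN = np.zeros((10, 4))
    for i, l in enumerate((l1, l2, l3, l4)):
        dN[i, i] = 4 * l - 1
    pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        dN[4 + k, i] = 4 * bary[j]
        dN[4 + k, j] = 4 * bary[i]
    return dN


def _assemble_stiffness(nodes: np.ndarray, conn: np.ndarray,
                        E: np.ndarray, nu: float, order: int
                        ) -> Tuple[sp.csr_matrix, np.ndarray]:
    """Global stiffness (CSR) and element volumes."""
    D = _elastic_d(E, nu)
    if order == 1:
        g, vol = _tet_gradients(nodes, conn)
        B = _b_matrix(g)
        DB = np.matmul(D, B)
        Ke = np.matmul(B.transpose(0, 2, 1), DB) * vol[:, None, None]
        nn = 4
    else:
        corner = conn[:, :4]
        J = nodes[corner][:, 1:] - nodes[corner][:, :1]
        vol = np.linalg.det(J) / 6.0
        Jinv = np.linalg.inv(J)
        # d lambda / d x: lambda_1..3 rows of Jinv^T, lambda_0 = -sum
        dLdx = np.empty((len(conn), 4, 3))
        dLdx[:, 1:, :] = Jinv.transpose(0, 2, 1)
        dLdx[:, 0, :] = -dLdx[:, 1:, :].sum(axis=1)
        # reorder to (λ1, λ2, λ3, λ4) = (node0..node3)
        Ke = np.zeros((len(conn), 30, 30))
        for gp in _GAUSS_TET4:
            dN = _tet10_shape_gradients(gp)           # (10, 4)
            gph = np.einsum("na,ead->end", dN, dLdx)  # (ne, 10, 3)
            B = _b_matrix(gph)
            Ke += np.matmul(B.transpose(0, 2, 1), np.matmul(D, B)) * (
                vol[:, None, None] / 4.0)
        nn = 10
    edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
        len(conn), 3 * nn)
    rows = np.repeat(edof, 3 * nn, axis=1).ravel()
    cols = np.tile(edof, (1, 3 * nn)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * len(nodes), 3 * len(nodes))).tocsr()
    return K, vol


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def _reduction(nodes: np.ndarray, lcm: LoadCaseModel
               ) -> Tuple[sp.csr_matrix, int]:
    """Constraint-elimination operator T with u_full = T u_red.

    Reduced layout: per-node dofs in node order (3 for free, 2 for
    trochanter-supported, 0 for fixed/cap), then 6 reference-point dofs
    (translation + rotation) at the end.
    """
    nn = len(nodes)
    kind = np.zeros(nn, dtype=np.int8)          # 0 free, 1 fixed, 2 cap, 3 troch
    kind[lcm.fixed_nodes] = 1
    kind[lcm.cap_nodes] = 2
    if lcm.config.troch_support == "rigid":
        kind[lcm.troch_nodes] = 3
    ndof_node = np.choose(kind, [3, 0, 0, 2])
    offsets = np.concatenate([[0], np.cumsum(ndof_node)])
    n_red = int(offsets[-1]) + 6
    ref0 = int(offsets[-1])

    rows, cols, vals = [], [], []
    free = np.where(kind == 0)[0]
    for c in range(3):
        rows.append(3 * free + c)
        cols.append(offsets[free] + c)
        vals.append(np.ones(len(free)))
    # trochanter: u = t1 a + t2 b with {a, b} spanning the plane ⟂ load axis
    axis = lcm.load_axis
    ref_v = np.array([1.0, 0, 0])
    if abs(axis @ ref_v) > 0.9:
        ref_v = np.array([0.0, 1.0, 0])
    a = np.cross(axis, ref_v)
    a /= np.linalg.norm(a)
    b = np.cross(axis, a)
    tro = np.where(kind == 3)[0]
    for c in range(3):
        rows.append(3 * tro + c)
        cols.append(offsets[tro] + 0)
        vals.append(np.full(len(tro), a[c]))
        rows.append(3 * tro + c)
        cols.append(offsets[tro] + 1)
        vals.append(np.full(len(tro), b[c]))
    # cap: rigid coupling u = u_ref + ω × (x − x_ref)
    cap = lcm.cap_nodes
    if len(cap):
        r = nodes[cap] - lcm.reference_point
        G = np.zeros((len(cap), 3, 6))
        G[:, 0, 0] = G[:, 1, 1] = G[:, 2, 2] = 1.0
        # u_c = u_t + ω × r  (ω in the last three ref dofs)
        G[:, 0, 4] = r[:, 2]
        G[:, 0, 5] = -r[:, 1]
        G[:, 1, 3] = -r[:, 2]
        G[:, 1, 5] = r[:, 0]
        G[:, 2, 3] = r[:, 1]
        G[:, 2, 4] = -r[:, 0]
        rr = (3 * cap[:, None, None] + np.arange(3)[None, :, None])
        cc = np.broadcast_to(ref0 + np.arange(6)[None, None, :],
                             (len(cap), 3, 6))
        rows.append(np.broadcast_to(rr, (len(cap), 3, 6)).ravel())
        cols.append(cc.ravel())
        vals.append(G.ravel())
    T = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * nn, n_red)).tocsr()
    return T, ref0


def _solve_reduced(K_red: sp.csr_matrix, f_red: np.ndarray, n_border: int
                   ) -> Tuple[np.ndarray, Dict[str, float]]:
    """Banded Cholesky with a dense Schur border; SuperLU fallback."""
    n = K_red.shape[0]
    nb = n - n_border
    diag: Dict[str, float] = {"n_dof": float(n)}
    A = K_red[:nb, :nb].tocoo()
    bw = int(np.max(np.abs(A.row - A.col))) if A.nnz else 0
    diag["bandwidth"] = float(bw)
    mem_gb = (bw + 1) * nb * 8 / 1e9
    if bw < 6000 and mem_gb < 5.0:
        try:
            # LAPACK upper-banded storage: ab[bw + i - j, j] = A[i, j]
            mask = A.row <= A.col
            flat = (bw + A.row[mask] - A.col[mask]).astype(np.int64) * nb \
                + A.col[mask]
            ab = np.bincount(flat, weights=A.data[mask],
                             minlength=(bw + 1) * nb).reshape(bw + 1, nb)
            cb = sla.cholesky_banded(ab, lower=False)
            Bm = np.asarray(K_red[:nb, nb:].todense())
            Cm = np.asarray(K_red[nb:, nb:].todense())
            AinvB = sla.cho_solve_banded((cb, False), Bm)
            x0 = sla.cho_solve_banded((cb, False), f_red[:nb])
            S = Cm - Bm.T @ AinvB
            ub = np.linalg.solve(S, f_red[nb:] - Bm.T @ x0)
            ua = x0 - AinvB @ ub
            diag["solver"] = 1.0  # banded
            return np.concatenate([ua, ub]), diag
        except np.linalg.LinAlgError as exc:
            raise RigidBodyModeError(
                f"banded factorisation failed (singular system?): {exc}"
            ) from exc
    try:
        lu = spla.splu(K_red.tocsc())
    except RuntimeError as exc:
        raise RigidBodyModeError(
            f"sparse factorisation failed (singular system?): {exc}") from exc
    diag["solver"] = 2.0  # SuperLU
    return lu.solve(f_red), diag


def assemble_and_solve(lcm: LoadCaseModel, order: int = 1
                       ) -> ElementStrainField:
    """Solve one load case at the reference load and return the strains.

    ``order=1`` uses constant-strain linear tets (default); ``order=2``
    upgrades the mesh to 10-node quadratic tets with straight edges.
    """
    if order not in (1, 2):
        raise ConfigurationError("element order must be 1 or 2")
    fm = lcm.model
    cfg = lcm.config
    if len(lcm.fixed_nodes) == 0:
        raise RigidBodyModeError("fixed node set is empty")
    E = np.where(fm.region == REGION_CORTICAL, cfg.E_cortical,
                 cfg.E_trabecular).astype(float)
    if order == 1:
        nodes, conn = fm.nodes, fm.tets
    else:
        nodes, conn = _quadratic_connectivity(fm.nodes, fm.tets)

    K, vol = _assemble_stiffness(nodes, conn, E, cfg.poisson, order)
    spring_k = None
    if len(lcm.troch_nodes) and cfg.troch_support == "foundation":
        # elastic polymer layer under the trochanter, acting along the
        # load axis: per-node stiffness = (E_emb / t_layer) * tributary area
        area = _tributary_areas(fm, lcm.troch_nodes,
                                apex=lcm.frame.gt_apex)
        spring_k = (cfg.E_embedding / cfg.troch_foundation_thickness) * area
        axis = lcm.load_axis
        block = np.outer(axis, axis)
        rows = (3 * lcm.troch_nodes[:, None, None]
                + np.arange(3)[None, :, None])
        cols = (3 * lcm.troch_nodes[:, None, None]
                + np.arange(3)[None, None, :])
        vals = spring_k[:, None, None] * block[None, :, :]
        K = K + sp.coo_matrix(
            (vals.ravel(),
             (np.broadcast_to(rows, vals.shape).ravel(),
              np.broadcast_to(cols, vals.shape).ravel())),
            shape=K.shape).tocsr()
    lcm2 = lcm
    if order == 2:
        # midside nodes on constrained faces/edges follow their corners
        lcm2 = dataclasses.replace(
            lcm,
            fixed_nodes=_augment_with_midside(lcm.fixed_nodes, conn),
            cap_nodes=_augment_with_midside(lcm.cap_nodes, conn),
            troch_nodes=_augment_with_midside(lcm.troch_nodes, conn),
        )
        both = np.intersect1d(lcm2.cap_nodes, lcm2.fixed_nodes)
        lcm2 = dataclasses.replace(
            lcm2, cap_nodes=np.setdiff1d(lcm2.cap_nodes, both))
    T, ref0 = _reduction(nodes, lcm2)
    K_red = (T.T @ K @ T).tocsr()
    f_red = np.zeros(K_red.shape[0])
    f_red[ref0: ref0 + 3] = cfg.F_ref * lcm.load_axis

    u_red, diag = _solve_reduced(K_red, f_red, 6)
    u = np.asarray(T @ u_red).ravel()

    # residual of the reduced system (machine-precision check)
    res = np.linalg.norm(K_red @ u_red - f_red) / max(
        np.linalg.norm(f_red), 1e-30)
    diag["residual"] = float(res)
    if res > 1e-6:
        raise AssemblyError(f"solver residual too large: {res:.2e}")

    # global equilibrium: reactions at fixed dofs plus the support
    # reactions (rigid patch forces or foundation spring forces) balance
    # the applied load
    r = np.asarray(K @ u).ravel().reshape(-1, 3)
    react = r[lcm2.fixed_nodes].sum(axis=0)
    if len(lcm2.troch_nodes):
        if cfg.troch_support == "rigid":
            tr = r[lcm2.troch_nodes].sum(axis=0)
            react = react + (tr @ lcm.load_axis) * lcm.load_axis
        else:
            un = u.reshape(-1, 3)[lcm.troch_nodes] @ lcm.load_axis
            react = react - float(spring_k @ un) * lcm.load_axis
    total = react + cfg.F_ref * lcm.load_axis
    diag["equilibrium_error"] = float(
        np.linalg.norm(total) / (cfg.F_ref))

    # element principal strains (centroid / averaged over Gauss points)
    if order == 1:
        g, _ = _tet_gradients(nodes, conn)
        ue = u.reshape(-1, 3)[conn]                     # (ne, 4, 3)
        grad = np.einsum("ean,ead->end", ue, g)         # du_n/dx_d
    else:
        corner = conn[:, :4]
        J = nodes[corner][:, 1:] - nodes[corner][:, :1]
        Jinv = np.linalg.inv(J)
        dLdx = np.empty((len(conn), 4, 3))
        dLdx[:, 1:, :] = Jinv.transpose(0, 2, 1)
        dLdx[:, 0, :] = -dLdx[:, 1:, :].sum(axis=1)
        ue = u.reshape(-1, 3)[conn]
        grad = np.zeros((len(conn), 3, 3))
        for gp in _GAUSS_TET4:
            dN = _tet10_shape_gradients(gp)
            gph = np.einsum("na,ead->end", dN, dLdx)
            grad += np.einsum("ean,ead->end", ue, gph) / 4.0
    eps = 0.5 * (grad + grad.transpose(0, 2, 1))
    prin = np.linalg.eigvalsh(eps)
    diag["max_displacement"] = float(np.abs(u).max())

    return ElementStrainField(
        e_max=prin[:, 2], e_min=prin[:, 0], volume=vol,
        region=fm.region.copy(), adjacency=face_adjacency(fm.tets),
        F_ref=cfg.F_ref, case=lcm.case, diagnostics=diag,
    )


def _tributary_areas(fm: FemurModel, nodeset: np.ndarray,
                     apex: Optional[np.ndarray] = None,
                     radius: float = _TROCH_PATCH_RADIUS) -> np.ndarray:
    """Surface area attributed to each node of ``nodeset`` (mm²).

    When ``apex`` is given, only faces whose centroid lies within
    ``radius`` of it contribute (the foundation patch), so the total
    spring stiffness tracks the true contact area at any mesh density.
    """
    areas = np.zeros(len(fm.nodes))
    faces = fm.surface_faces
    w = np.ones(len(faces))
    if apex is not None:
        fc = fm.nodes[faces].mean(axis=1)
        d = np.linalg.norm(fc - apex, axis=1)
        inside = d <= radius
        faces = faces[inside]
        d = d[inside]
        # cosine taper from the full-stiffness core to the patch rim keeps
        # the foundation edge smooth (a sharp stiffness step concentrates
        # surface strain and spoils mesh convergence)
        w = np.where(
            d <= _TROCH_PATCH_CORE, 1.0,
            np.cos(0.5 * np.pi * (d - _TROCH_PATCH_CORE)
                   / max(radius - _TROCH_PATCH_CORE, 1e-9)) ** 2)
    tri = fm.nodes[faces]
    a = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    a = a * w
    for c in range(3):
        np.add.at(areas, faces[:, c], a / 3.0)
    return areas[nodeset]


def solve_displacement(nodes: np.ndarray, tets: np.ndarray, E: np.ndarray,
                       nu: float, fixed_nodes: np.ndarray,
                       forces: np.ndarray, order: int = 1
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Generic small-strain solve: fixed nodes, nodal forces.

    Returns the displacement field (per original node for ``order=2``
    the midside values are appended) and per-element principal strains
    (ne, 3).  Used for verification problems (patch test, cantilever)
    and available for ad-hoc analyses.
    """
    E = np.asarray(E, dtype=float)
    if order == 2:
        nodes_a, conn = _quadratic_connectivity(np.asarray(nodes), tets)
        fixed_nodes = _augment_with_midside(np.asarray(fixed_nodes), conn)
        forces = np.vstack([forces,
                            np.zeros((len(nodes_a) - len(nodes), 3))])
        nodes = nodes_a
    else:
        nodes = np.asarray(nodes)
        conn = tets
    K, _ = _assemble_stiffness(nodes, conn, E, nu, order)
    free = np.setdiff1d(np.arange(len(nodes)), fixed_nodes)
    dofs = (3 * free[:, None] + np.arange(3)[None, :]).ravel()
    Kff = K[dofs][:, dofs].tocsc()
    f = np.asarray(forces, dtype=float).ravel()[dofs]
    try:
        uf = spla.spsolve(Kff, f)
    except RuntimeError as exc:
        raise RigidBodyModeError(str(exc)) from exc
    if not np.all(np.isfinite(uf)):
        raise RigidBodyModeError("singular system (free rigid-body mode)")
    u = np.zeros((len(nodes), 3))
    u[free] = uf.reshape(-1, 3)
    if order == 1:
        g, _ = _tet_gradients(nodes, conn)
        grad = np.einsum("ean,ead->end", u[conn], g)
    else:
        corner = conn[:, :4]
        J = nodes[corner][:, 1:] - nodes[corner][:, :1]
        Jinv = np.linalg.inv(J)
        dLdx = np.empty((len(conn), 4, 3))
        dLdx[:, 1:, :] = Jinv.transpose(0, 2, 1)
        dLdx[:, 0, :] = -dLdx[:, 1:, :].sum(axis=1)
        grad = np.zeros((len(conn), 3, 3))
        for gp in _GAUSS_TET4:
            dN = _tet10_shape_gradients(gp)
            gph = np.einsum("na,ead->end", dN, dLdx)
            grad += np.einsum("ean,ead->end", u[conn], gph) / 4.0
    eps = 0.5 * (grad + grad.transpose(0, 2, 1))
    return u, np.linalg.eigvalsh(eps)


def _augment_with_midside(nodeset: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Add midside nodes whose both edge endpoints are in ``nodeset``."""
    if len(nodeset) == 0:
        return nodeset
    inset = np.zeros(conn.max() + 1, dtype=bool)
    inset[nodeset] = True
    pairs = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    extra = []
    for k, (i, j) in enumerate(pairs):
        sel = inset[conn[:, i]] & inset[conn[:, j]]
        extra.append(conn[sel, 4 + k])
    return np.unique(np.concatenate([nodeset, *extra]))
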