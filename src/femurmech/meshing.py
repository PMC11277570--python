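"""Structured tetrahedral meshing of the parametric femur.

The solid is swept level by level along the shaft axis: each level is a
polar disk (centre node, trabecular rings, cortical rings, surface ring)
around the star-centre curve, with one ring placed exactly on the
cortical/trabecular interface so that the two regions share interface
nodes by construction.  Ring sectors between consecutive levels form
prisms and hexahedra; hexahedra are cut into two prisms by a fixed
diagonal plane and every prism is split into three tetrahedra with the
minimum-vertex-index rule, which makes the split conforming across all
shared faces.  The head apex is closed by a cone of tetrahedra onto a
single node placed exactly on the head sphere.

Feature levels are inserted exactly at the distal end, the 2/3-length
cut plane, just below the greater-trochanter apex, and in a graded band
under the head apex, so the quantities measured from the mesh (total
length, trochanter height, trimmed extent) are not limited by the level
spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import ConstructionError, DegenerateGeometryError
from .geometry import (
    PART_DISTAL,
    PART_HEAD,
    PART_NONE,
    ParametricFemur,
)
from .params import GeneratorConfig, MorphologySet

__all__ = ["FemurModel", "build_geometry", "trim_and_embed", "prisms_to_tets"]

REGION_TRABECULAR = 0
REGION_CORTICAL = 1

# crease-fillet smoothing lengths of the swept limit surface
# (z in mm on the 1 mm fine grid; theta in fine-grid steps of ~2.8 deg)
_FILLET_SIGMA_Z = 4.0
_FILLET_SIGMA_THETA = 4.0

# prism symmetries bringing local vertex p to position 0 (bottom 0-1-2, top 3-4-5)
_PRISM_SYM = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 5, 4, 0, 2, 1],
    [4, 3, 5, 1, 0, 2],
    [5, 4, 3, 2, 1, 0],
], dtype=np.int64)

# tet templates after canonical rotation; choice depends on the free face diagonal
_TET_A = np.array([[0, 1, 2, 5], [0, 1, 5, 4], [0, 4, 5, 3]], dtype=np.int64)
_TET_B = np.array([[0, 1, 2, 4], [0, 4, 2, 5], [0, 4, 5, 3]], dtype=np.int64)


def prisms_to_tets(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (n, 6) into tets (3n, 4) with the min-vertex rule.

    Quad-face diagonals always pass through the face's smallest global
    node id, so two cells sharing a quad face produce the same two
    triangles — the resulting tetrahedralisation is conforming.
    """
    prisms = np.asarray(prisms, dtype=np.int64)
    n = prisms.shape[0]
    pos = np.argmin(prisms, axis=1)
    canon = np.take_along_axis(prisms, _PRISM_SYM[pos], axis=1)
    # free face is (1, 2, 5, 4); diagonal through its min vertex
    face = canon[:, [1, 2, 5, 4]]
    fmin = np.argmin(face, axis=1)
    use_a = (fmin == 0) | (fmin == 2)      # min at local 1 or 5 -> diagonal 1-5
    tets = np.empty((n, 3, 4), dtype=np.int64)
    tets[use_a] = np.take_along_axis(
        canon[use_a, None, :], np.broadcast_to(_TET_A, (use_a.sum(), 3, 4)), axis=2)
    not_a = ~use_a
    tets[not_a] = np.take_along_axis(
        canon[not_a, None, :], np.broadcast_to(_TET_B, (not_a.sum(), 3, 4)), axis=2)
    return tets.reshape(-1, 4)


@dataclass
class FemurModel:
    """Labelled tetrahedral solid of one femur with landmarks.

    Coordinates in mm.  ``region`` is 1 for cortical, 0 for trabecular
    elements.  ``node_tags`` carries the surface part tag per node
    (−1 for interior nodes).  The ``landmarks`` dict stores the
    constructed anatomical frame of the generator (head centre, shaft and
    neck axes, condylar axis/centre, trochanter apex, lesser-trochanter
    centre); ``ground_truth`` is the morphology the femur was built from.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_tags: np.ndarray
    landmarks: Dict[str, np.ndarray]
    ground_truth: Optional[MorphologySet] = None
    config: Optional[GeneratorConfig] = None
    cut_z: Optional[float] = None
    trimmed: bool = False
    embedded_nodes: Optional[np.ndarray] = None
    surface_faces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.surface_faces is None:
            self.surface_faces = boundary_faces(self.tets)

    # -------------------------------------------------------------- helpers

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        m = x[:, 1:] - x[:, :1]
        return np.linalg.det(m) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def surface_nodes(self, tag: Optional[int] = None) -> np.ndarray:
        idx = np.unique(self.surface_faces)
        if tag is None:
            return idx
        return idx[self.node_tags[idx] == tag]

    def transform(self, rotation: np.ndarray, translation: np.ndarray
                  ) -> "FemurModel":
        """Rigidly transformed copy (landmark points and axes follow)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        lm = {}
        for key, val in self.landmarks.items():
            v = np.asarray(val, dtype=float)
            if key.endswith("_dir") or key.endswith("_axis") or key == "condylar_axis":
                lm[key] = R @ v
            else:
                lm[key] = R @ v + t
        return dataclasses.replace(
            self,
            nodes=self.nodes @ R.T + t,
            tets=self.tets.copy(),
            region=self.region.copy(),
            node_tags=self.node_tags.copy(),
            landmarks=lm,
            surface_faces=self.surface_faces.copy(),
            embedded_nodes=None if self.embedded_nodes is None
            else self.embedded_nodes.copy(),
        )


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces owned by exactly one tetrahedron (the solid's surface)."""
    faces = tets[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return faces[counts[inv] == 1]


def _level_grid(pf: ParametricFemur, h: float) -> np.ndarray:
    """z positions of the sweep levels, with exact feature levels."""
    z0, z1 = pf.z_end, pf.z_top
    graded = z1 - np.array([0.2, 0.7, 1.6, 3.0])
    features = [z0, pf.z_cut, pf.z_apex - 0.2, *graded]
    features = sorted(set(round(f, 6) for f in features if z0 <= f < z1))
    base = np.arange(z0, z1 - 3.0, h)
    keep = list(features)
    for z in base:
        if all(abs(z - f) >= 0.3 * h for f in keep):
            keep.append(round(float(z), 6))
    return np.array(sorted(keep))


def build_geometry(m: MorphologySet, config: GeneratorConfig) -> FemurModel:
    """Construct the labelled tetrahedral solid for one morphology set."""
    config.validate()
    pf = ParametricFemur(m, config)
    h = config.edge_length
    t_sh = config.cortical_thickness["shaft"] * config.thickness_scale

    zs = _level_grid(pf, h)
    nlev = len(zs)
    ntheta = max(16, int(round(2.0 * np.pi * config.reference_radius / h)))
    ntheta += ntheta % 2
    n_in = max(2, int(round((config.reference_radius - t_sh) / h)))
    # at least two through-thickness cortical layers at any edge length:
    # the fracture criterion samples centroid strains across the shell's
    # bending gradient, and tying the layer count to the edge length would
    # re-discretise that gradient on every refinement
    nc = max(2, int(round(t_sh / h)))
    nr = n_in + nc
    theta = np.linspace(0.0, 2.0 * np.pi, ntheta, endpoint=False)

    # sweep the analytic cross-sections on a fixed fine (θ, z) grid, drape
    # and fillet there, then sample the resulting limit surface at the
    # mesh levels/azimuths — every mesh density discretises the *same*
    # smooth solid
    from scipy.ndimage import gaussian_filter1d

    from .geometry import PART_TROCH, _DRAPE_SLOPE
    ntheta_f = 128
    theta_f = np.linspace(0.0, 2.0 * np.pi, ntheta_f, endpoint=False)
    zs_fine = np.unique(np.concatenate(
        [np.arange(pf.z_end, pf.z_top, 1.0), zs]))
    nfine = len(zs_fine)
    Rf = np.empty((nfine, ntheta_f))
    tagf = np.empty((nfine, ntheta_f), dtype=np.int8)
    for l, z in enumerate(zs_fine):
        R, tg = pf.cross_section(float(z), theta_f)
        if not np.all(np.isfinite(R)) or np.any(R <= 0.5):
            raise ConstructionError(
                f"degenerate cross-section at z={z:.2f} "
                f"(morphology not constructible at this level)")
        Rf[l] = R
        tagf[l] = tg
    r_orig = Rf.copy()

    # Lipschitz drape along z: bound |dR/dz| by raising the smaller side,
    # so steep part transitions cannot fold the swept mesh over
    for l in range(nfine - 2, -1, -1):
        dz = zs_fine[l + 1] - zs_fine[l]
        np.maximum(Rf[l], Rf[l + 1] - _DRAPE_SLOPE * dz, out=Rf[l])
    for l in range(1, nfine):
        dz = zs_fine[l] - zs_fine[l - 1]
        np.maximum(Rf[l], Rf[l - 1] - _DRAPE_SLOPE * dz, out=Rf[l])

    # fillet reentrant creases: morphological closing with a Gaussian
    # (raise-only), because surface creases act as notches that
    # concentrate surface strain; the lift is capped to 0.15 mm on named
    # part surfaces (their geometry carries the measured parameters, e.g.
    # the neck-waist valley realises ND) and unrestricted on junction
    # fillets
    smooth = gaussian_filter1d(Rf, sigma=_FILLET_SIGMA_Z, axis=0,
                               mode="nearest")
    smooth = gaussian_filter1d(smooth, sigma=_FILLET_SIGMA_THETA, axis=1,
                               mode="wrap")
    cap = np.where(tagf == PART_NONE, np.inf, 0.15)
    np.maximum(Rf, np.minimum(smooth, r_orig + cap), out=Rf)

    lift = Rf - r_orig
    # lifted surface is junction fillet; the trochanter tag tolerates a
    # moderate lateral lift (only its axial position is ever measured)
    retag = (lift > 0.3) & ~((tagf == PART_TROCH) & (lift <= 2.0))
    tagf[retag] = PART_NONE

    # sample the limit surface at the mesh levels and azimuths
    sel = np.searchsorted(zs_fine, zs)
    if not np.allclose(zs_fine[sel], zs, atol=1e-9):
        raise ConstructionError("mesh level missing from fine grid")
    tf_ext = np.concatenate([theta_f, [2.0 * np.pi]])
    Rg = np.empty((nlev, ntheta))
    tag = np.empty((nlev, ntheta), dtype=np.int8)
    step = 2.0 * np.pi / ntheta_f
    j_lo = np.floor(theta / step).astype(int) % ntheta_f
    j_hi = (j_lo + 1) % ntheta_f
    for i, j in enumerate(sel):
        row = np.concatenate([Rf[j], Rf[j, :1]])
        Rg[i] = np.interp(theta, tf_ext, row)
        # tags at mesh azimuths: nearest fine azimuth by default; the head
        # tag additionally requires both bracketing azimuths to agree
        # (sphere-fit nodes must lie on the sphere, and interpolated radii
        # at part boundaries are chords); the trochanter tag survives if
        # either neighbour carries it (its azimuthal footprint near the
        # apex is narrow and only its axial position is measured)
        lo, hi = tagf[j, j_lo], tagf[j, j_hi]
        near = np.where(theta - (j_lo * step) <= 0.5 * step, lo, hi)
        t_row = near.copy()
        t_row[(t_row == PART_HEAD) & (lo != hi)] = PART_NONE
        t_row[(lo == PART_TROCH) | (hi == PART_TROCH)] = PART_TROCH
        tag[i] = t_row

    # cortical thickness field from surface tags, smoothed, clamped
    tk = pf.thickness_for_tag(tag)
    tk = uniform_filter1d(tk, size=7, axis=1, mode="wrap")
    tk = uniform_filter1d(tk, size=5, axis=0, mode="nearest")
    tk = np.minimum(tk, 0.45 * Rg)

    # nodes: centre + n_in trabecular rings (interface ring last) + nc cortical
    cx, cy = pf.centre(zs)
    npl = 1 + nr * ntheta
    nodes = np.empty((nlev * npl + 1, 3))
    ct, st = np.cos(theta), np.sin(theta)
    frac_in = np.arange(1, n_in + 1) / n_in
    frac_c = np.arange(1, nc + 1) / nc
    for l in range(nlev):
        base = l * npl
        nodes[base] = (cx[l], cy[l], zs[l])
        r_if = Rg[l] - tk[l]
        radii = np.concatenate([
            frac_in[:, None] * r_if[None, :],
            r_if[None, :] + frac_c[:, None] * tk[l][None, :],
        ])                                    # (nr, ntheta)
        ring = np.empty((nr, ntheta, 3))
        ring[..., 0] = cx[l] + radii * ct
        ring[..., 1] = cy[l] + radii * st
        ring[..., 2] = zs[l]
        nodes[base + 1: base + npl] = ring.reshape(-1, 3)
    apex = nlev * npl
    nodes[apex] = (cx[-1], cy[-1], pf.z_top)

    def nid(l, j, k):
        """Node id at level l, ring j (1-based; 0 = centre), azimuth k."""
        return l * npl + 1 + (j - 1) * ntheta + (k % ntheta)

    L = np.arange(nlev - 1)
    K = np.arange(ntheta)
    Lg, Kg = np.meshgrid(L, K, indexing="ij")
    prisms = []
    cell_ring = []
    # centre wedges
    c0 = (Lg * npl).ravel()
    c1 = ((Lg + 1) * npl).ravel()
    a0 = nid(Lg, 1, Kg).ravel()
    a1 = nid(Lg, 1, Kg + 1).ravel()
    b0 = nid(Lg + 1, 1, Kg).ravel()
    b1 = nid(Lg + 1, 1, Kg + 1).ravel()
    prisms.append(np.stack([c0, a0, a1, c1, b0, b1], axis=1))
    cell_ring.append(np.zeros(c0.size, dtype=np.int32))
    # ring sector hexes -> two prisms by the fixed (j,k)->(j+1,k+1) diagonal
    for j in range(1, nr):
        A0 = nid(Lg, j, Kg).ravel()
        B0 = nid(Lg, j + 1, Kg).ravel()
        C0 = nid(Lg, j + 1, Kg + 1).ravel()
        D0 = nid(Lg, j, Kg + 1).ravel()
        A1 = nid(Lg + 1, j, Kg).ravel()
        B1 = nid(Lg + 1, j + 1, Kg).ravel()
        C1 = nid(Lg + 1, j + 1, Kg + 1).ravel()
        D1 = nid(Lg + 1, j, Kg + 1).ravel()
        prisms.append(np.stack([A0, B0, C0, A1, B1, C1], axis=1))
        prisms.append(np.stack([A0, C0, D0, A1, C1, D1], axis=1))
        cell_ring.append(np.full(A0.size, j, dtype=np.int32))
        cell_ring.append(np.full(A0.size, j, dtype=np.int32))
    prisms = np.concatenate(prisms)
    cell_ring = np.concatenate(cell_ring)
    tets = prisms_to_tets(prisms)
    ring_of_tet = np.repeat(cell_ring, 3)

    # apex cap: cone of tets from the top-level disk onto the apex node
    lt = nlev - 1
    cap_tets = []
    cap_ring = []
    a0 = nid(lt, 1, K)
    a1 = nid(lt, 1, K + 1)
    cap_tets.append(np.stack([np.full(ntheta, lt * npl), a0, a1,
                              np.full(ntheta, apex)], axis=1))
    cap_ring.append(np.zeros(ntheta, dtype=np.int32))
    for j in range(1, nr):
        A = nid(lt, j, K)
        B = nid(lt, j + 1, K)
        C = nid(lt, j + 1, K + 1)
        D = nid(lt, j, K + 1)
        # same fixed diagonal A-C as the hex split below
        cap_tets.append(np.stack([A, B, C, np.full(ntheta, apex)], axis=1))
        cap_tets.append(np.stack([A, C, D, np.full(ntheta, apex)], axis=1))
        cap_ring.append(np.full(ntheta, j, dtype=np.int32))
        cap_ring.append(np.full(ntheta, j, dtype=np.int32))
    tets = np.concatenate([tets, np.concatenate(cap_tets)])
    ring_of_tet = np.concatenate([ring_of_tet, np.concatenate(cap_ring)])

    # orient and validate
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    neg = vol < 0
    tets[neg] = tets[neg][:, [1, 0, 2, 3]]
    vol = np.abs(vol)
    if np.any(vol < 1e-9):
        raise ConstructionError(
            f"{int(np.sum(vol < 1e-9))} degenerate tetrahedra in swept mesh")

    region = np.where(ring_of_tet >= nr - nc, REGION_CORTICAL,
                      REGION_TRABECULAR).astype(np.uint8)
    # the greater trochanter is modelled as dense bone throughout: the
    # fall-case support reaction enters there, and the homogeneous
    # two-phase material lacks the densified trabecular struts that carry
    # it in vivo, so a soft-cored bump would concentrate all load in its
    # thin shell
    from .geometry import _TROCH_AX, _TROCH_AY, _TROCH_AZ
    cent = nodes[tets].mean(axis=1)
    rel = (cent - pf.troch_centre) / np.array(
        [_TROCH_AX, _TROCH_AY, _TROCH_AZ])
    region[np.einsum("ij,ij->i", rel, rel) <= 1.0] = REGION_CORTICAL

    # node surface tags
    node_tags = np.full(len(nodes), -1, dtype=np.int8)
    for l in range(nlev):
        node_tags[nid(l, nr, K)] = tag[l]
    node_tags[:npl] = PART_DISTAL            # distal cut disk
    node_tags[apex] = PART_HEAD

    model = FemurModel(
        nodes=nodes, tets=tets, region=region, node_tags=node_tags,
        landmarks=pf.landmarks(), ground_truth=m, config=config,
        cut_z=pf.z_cut,
    )
    return model


def trim_and_embed(fm: FemurModel, embedding_depth: float = 70.0
                   ) -> FemurModel:
    """Cut the femur at 2/3 of its length and flag the embedded node set.

    Elements whose centroid lies distal to the cut plane (2/3 of the
    total femur length from the proximal end) are removed; surface nodes
    within ``embedding_depth`` mm of the distal cut end are flagged as
    the fixed (embedded) set.  Calling this on an already trimmed model
    is a no-op apart from refreshing the embedded set.
    """
    if fm.cut_z is None:
        raise DegenerateGeometryError("model has no recorded cut plane")
    z = fm.tet_centroids()[:, 2]
    if fm.cut_z >= fm.nodes[:, 2].max():
        raise DegenerateGeometryError("cut plane lies proximal to the mesh")
    keep = z >= fm.cut_z if not fm.trimmed else np.ones(len(z), dtype=bool)
    if not fm.trimmed and not np.any(~keep):
        raise DegenerateGeometryError("cut plane intersects no elements")
    tets = fm.tets[keep]
    used = np.unique(tets)
    remap = -np.ones(len(fm.nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new = dataclasses.replace(
        fm,
        nodes=fm.nodes[used],
        tets=remap[tets],
        region=fm.region[keep],
        node_tags=fm.node_tags[used],
        landmarks=dict(fm.landmarks),
        trimmed=True,
        surface_faces=None,
    )
    zmin = new.nodes[:, 2].min()
    surf = new.surface_nodes()
    new.embedded_nodes = surf[new.nodes[surf, 2] <= zmin + embedding_depth]
    return new
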