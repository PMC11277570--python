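"""Constructive geometry and swept meshing: landmarks, validity, trimming."""

import dataclasses
import math

import numpy as np
import pytest

from femurmech.errors import ConstructionError, DegenerateGeometryError
from femurmech.geometry import PART_HEAD, PART_NECK, ParametricFemur
from femurmech.meshing import (
    REGION_CORTICAL,
    REGION_TRABECULAR,
    boundary_faces,
    build_geometry,
    prisms_to_tets,
    trim_and_embed,
)
from femurmech.params import GeneratorConfig, sample_morphologies
from conftest import make_box_mesh, mean_calibration


def replace_param(m, **kw):
    return dataclasses.replace(m, **kw)


# --------------------------------------------------------------- construction

def test_zero_antetorsion_head_centre_lies_in_frontal_plane(coarse_config):
    cal = mean_calibration()
    from femurmech.params import ParamCalibration
    cal["ATA"] = ParamCalibration(0.0, 0.0, -1.0, 1.0)
    cal["DCHD"] = ParamCalibration(0.0, 0.0, -1.0, 1.0)
    cal["DCVD"] = ParamCalibration(0.0, 0.0, -1.0, 1.0)
    cfg = coarse_config.replace(calibration=cal)
    m = sample_morphologies(cfg)[0]
    pf = ParametricFemur(m, cfg)
    assert pf.fhc[1] == pytest.approx(0.0, abs=1e-9)
    assert m.OSA == pytest.approx(m.OSH, rel=1e-9)


def test_head_sphere_diameter_matches_morphology(mean_femur, mean_morphology):
    idx = mean_femur.surface_nodes(PART_HEAD)
    d = np.linalg.norm(mean_femur.nodes[idx] - mean_femur.landmarks["fhc"],
                       axis=1)
    # head nodes lie on the sphere up to the 0.15 mm crease-fillet cap
    assert np.abs(2 * d - mean_morphology.FHD).max() < 0.35


def test_head_offset_from_shaft_axis_closed_form(coarse_config):
    """Zero offsets, zero antetorsion: FHC-to-FSA distance = FNAL sin(NSA)."""
    cal = mean_calibration()
    from femurmech.params import ParamCalibration
    for name in ("ATA", "DCHD", "DCVD"):
        cal[name] = ParamCalibration(0.0, 0.0, -1.0, 1.0)
    cfg = coarse_config.replace(calibration=cal)
    m = sample_morphologies(cfg)[0]
    pf = ParametricFemur(m, cfg)
    # shaft axis is the z axis through the origin in the canonical frame;
    # independent triangle geometry: perpendicular arm = FNAL sin(NSA)
    dist = math.hypot(pf.fhc[0], pf.fhc[1])
    assert dist == pytest.approx(
        m.FNAL * math.sin(math.radians(m.NSA)), rel=1e-9)
    assert m.OSH == pytest.approx(dist, rel=1e-9)


def test_infeasible_neck_raises_construction_error(coarse_config,
                                                   mean_morphology):
    bad = replace_param(mean_morphology, FNAL=20.0)
    with pytest.raises(ConstructionError):
        ParametricFemur(bad, coarse_config)


# -------------------------------------------------------------------- meshing

def test_mesh_is_valid_conforming_and_watertight(mean_femur):
    vol = mean_femur.tet_volumes()
    assert np.all(vol > 0), "inverted tetrahedra"
    faces = mean_femur.tets[:, [[0, 1, 2], [0, 1, 3],
                                [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    assert set(counts.tolist()) <= {1, 2}, "non-conforming faces"
    edges = np.sort(mean_femur.surface_faces[
        :, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1)
    _, ecnt = np.unique(edges, axis=0, return_counts=True)
    assert np.all(ecnt == 2), "surface is not watertight"


def test_cortical_shell_separates_trabecular_from_surface(mean_femur):
    """Every boundary face belongs to a cortical element."""
    face_owner = {}
    faces = mean_femur.tets[:, [[0, 1, 2], [0, 1, 3],
                                [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    owner = np.repeat(np.arange(len(mean_femur.tets)), 4)
    key = [tuple(sorted(f)) for f in faces]
    from collections import Counter
    cnt = Counter(key)
    surface_owners = {k: o for k, o in zip(key, owner) if cnt[k] == 1}
    regions = mean_femur.region[list(surface_owners.values())]
    # distal cut disk exposes trabecular bone; everywhere else cortical
    zcut = mean_femur.nodes[:, 2].min() + 1.0
    exposed = [o for k, o in surface_owners.items()
               if mean_femur.region[o] == REGION_TRABECULAR]
    for o in exposed:
        assert mean_femur.tet_centroids()[o, 2] < zcut + 5.0


def test_regions_share_interface_nodes(mean_femur):
    """Conforming bi-material mesh: interface nodes used by both regions."""
    cort = np.unique(mean_femur.tets[mean_femur.region == REGION_CORTICAL])
    trab = np.unique(mean_femur.tets[mean_femur.region == REGION_TRABECULAR])
    shared = np.intersect1d(cort, trab)
    assert len(shared) > 0.1 * len(trab)


def test_total_length_realised_exactly(mean_femur, mean_morphology):
    z = mean_femur.nodes[:, 2]
    assert z.max() - z.min() == pytest.approx(mean_morphology.TFL, abs=1e-6)


def test_prism_split_is_conforming_on_a_box():
    nodes, tets = make_box_mesh(3, 3, 3, 3, 3, 3)
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    assert np.all(np.abs(vol) > 0)
    assert np.isclose(np.abs(vol).sum(), 27.0)
    faces = np.sort(tets[:, [[0, 1, 2], [0, 1, 3],
                             [0, 2, 3], [1, 2, 3]]].reshape(-1, 3), axis=1)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    assert set(counts.tolist()) <= {1, 2}


def test_prism_split_respects_min_vertex_diagonals():
    prism = np.array([[10, 3, 7, 2, 9, 4]])
    tets = prisms_to_tets(prism)
    assert tets.shape == (3, 4)
    # volume partition of the reference prism
    coords = {10: (0, 0, 0), 3: (1, 0, 0), 7: (0, 1, 0),
              2: (0, 0, 1), 9: (1, 0, 1), 4: (0, 1, 1)}
    v = 0.0
    for t in tets:
        p = np.array([coords[i] for i in t], dtype=float)
        v += abs(np.linalg.det(p[1:] - p[0]) / 6.0)
    assert v == pytest.approx(0.5)


# ------------------------------------------------------------------- trimming

def test_trim_keeps_two_thirds_of_the_length(mean_femur, mean_morphology):
    trimmed = trim_and_embed(mean_femur)
    z = trimmed.nodes[:, 2]
    assert z.max() - z.min() == pytest.approx(
        2.0 * mean_morphology.TFL / 3.0, abs=mean_femur.config.edge_length)


def test_trim_is_idempotent(trimmed_mean_femur):
    again = trim_and_embed(trimmed_mean_femur)
    assert len(again.tets) == len(trimmed_mean_femur.tets)
    assert np.array_equal(again.tets, trimmed_mean_femur.tets)


def test_embedded_set_matches_brute_force_scan(trimmed_mean_femur):
    fm = trimmed_mean_femur
    surf = fm.surface_nodes()
    zmin = fm.nodes[:, 2].min()
    brute = surf[fm.nodes[surf, 2] <= zmin + 70.0]
    assert np.array_equal(np.sort(fm.embedded_nodes), np.sort(brute))


def test_trim_without_cut_plane_raises(mean_femur):
    broken = dataclasses.replace(mean_femur, cut_z=None,
                                 surface_faces=mean_femur.surface_faces)
    with pytest.raises(DegenerateGeometryError):
        trim_and_embed(broken)


def test_rigid_transform_moves_mesh_and_landmarks_together(mean_femur):
    ang = 0.7
    R = np.array([[math.cos(ang), -math.sin(ang), 0],
                  [math.sin(ang), math.cos(ang), 0],
                  [0, 0, 1.0]]) @ np.array(
        [[1, 0, 0], [0, math.cos(0.3), -math.sin(0.3)],
         [0, math.sin(0.3), math.cos(0.3)]])
    t = np.array([10.0, -4.0, 2.5])
    moved = mean_femur.transform(R, t)
    assert np.allclose(moved.nodes[0], R @ mean_femur.nodes[0] + t)
    assert np.allclose(moved.landmarks["fhc"],
                       R @ mean_femur.landmarks["fhc"] + t)
    assert np.allclose(moved.landmarks["shaft_axis_dir"],
                       R @ mean_femur.landmarks["shaft_axis_dir"])
    assert np.allclose(moved.tet_volumes(), mean_femur.tet_volumes())
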