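"""Shared fixtures: small meshes and femur models built once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from femurmech.meshing import build_geometry, prisms_to_tets, trim_and_embed
from femurmech.params import (
    DEFAULT_CALIBRATION,
    GeneratorConfig,
    ParamCalibration,
    sample_morphologies,
)


def make_box_mesh(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float):
    """Structured tetrahedral box mesh (conforming prism splits)."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    prisms = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                a, b = nid(i, j, k), nid(i + 1, j, k)
                c, d = nid(i + 1, j + 1, k), nid(i, j + 1, k)
                a1, b1 = nid(i, j, k + 1), nid(i + 1, j, k + 1)
                c1, d1 = nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)
                prisms.append([a, b, c, a1, b1, c1])
                prisms.append([a, c, d, a1, c1, d1])
    tets = prisms_to_tets(np.array(prisms))
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1])
    tets[vol < 0] = tets[vol < 0][:, [1, 0, 2, 3]]
    return nodes, tets


def mean_calibration():
    return {k: ParamCalibration(v.mean, 0.0, v.lo, v.hi)
            for k, v in DEFAULT_CALIBRATION.items()}


@pytest.fixture(scope="session")
def mean_morphology():
    cfg = GeneratorConfig(cohort_size=1, seed=0,
                          calibration=mean_calibration())
    return sample_morphologies(cfg)[0]


@pytest.fixture(scope="session")
def coarse_config():
    """Coarse mesh settings for fast structural tests."""
    return GeneratorConfig(cohort_size=1, seed=0, edge_length=4.0)


@pytest.fixture(scope="session")
def mean_femur(mean_morphology, coarse_config):
    return build_geometry(mean_morphology, coarse_config)


@pytest.fixture(scope="session")
def trimmed_mean_femur(mean_femur):
    return trim_and_embed(mean_femur)


@pytest.fixture(scope="session")
def measured_mean(trimmed_mean_femur):
    from femurmech.morphometry import build_frame, measure

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame = build_frame(trimmed_mean_femur)
        return frame, measure(trimmed_mean_femur, frame)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = GeneratorConfig(cohort_size=6, seed=11, edge_length=4.5)
    return cfg, sample_morphologies(cfg)
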