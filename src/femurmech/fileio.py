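"""Readers and writers for the mesh and table formats used by the pipeline.

Solid meshes travel as legacy ASCII VTK unstructured grids (tet cells
with region/cell data) or Abaqus-style INP text; surfaces as STL/PLY
via :mod:`trimesh`; tables as CSV with the parameter abbreviations as
column headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .meshing import FemurModel
from .params import PARAMETER_NAMES, MorphologySet

__all__ = [
    "write_vtk", "read_vtk", "write_inp", "write_surface_stl",
    "morphologies_to_csv", "morphologies_from_csv", "write_json",
]

PathLike = Union[str, Path]


def write_vtk(path: PathLike, nodes: np.ndarray, tets: np.ndarray,
              cell_data: Optional[Dict[str, np.ndarray]] = None,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              title: str = "femurmech unstructured grid") -> None:
    """Legacy ASCII VTK unstructured grid with linear tet cells."""
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(len(tets), 4), tets]), fmt="%d")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        np.savetxt(fh, np.full(len(tets), 10), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {len(tets)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\n"
                             "LOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")


def read_vtk(path: PathLike) -> Tuple[np.ndarray, np.ndarray,
                                      Dict[str, np.ndarray]]:
    """Read the tet mesh back from a legacy ASCII VTK file.

    Returns (nodes, tets, cell_data).  Only the subset written by
    :func:`write_vtk` is supported.
    """
    tokens: list = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    nodes = tets = None
    cell_data: Dict[str, np.ndarray] = {}
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in lines[i].split())
                i += 1
            nodes = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("CELLS"):
            n = int(line.split()[1])
            rows = []
            i += 1
            for _ in range(n):
                parts = lines[i].split()
                rows.append([int(t) for t in parts[1:]])
                i += 1
            tets = np.array(rows, dtype=np.int64)
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while i < len(lines) and len(vals) < len(tets):
                s = lines[i].strip()
                if not s or not s[0] in "-0123456789.":
                    break
                vals.extend(float(t) for t in s.split())
                i += 1
            cell_data[name] = np.array(vals)
            continue
        i += 1
    if nodes is None or tets is None:
        raise ValueError(f"{path}: not a femurmech VTK tet mesh")
    return nodes, tets, cell_data


def write_inp(path: PathLike, fm: FemurModel) -> None:
    """Abaqus-style text mesh: nodes, C3D4 elements, region element sets."""
    with open(path, "w") as fh:
        fh.write("*HEADING\nfemurmech tetrahedral femur model\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(fm.nodes, start=1):
            fh.write(f"{i}, {x:.6f}, {y:.6f}, {z:.6f}\n")
        fh.write("*ELEMENT, TYPE=C3D4, ELSET=ALL\n")
        for e, t in enumerate(fm.tets + 1, start=1):
            fh.write(f"{e}, {t[0]}, {t[1]}, {t[2]}, {t[3]}\n")
        for name, code in (("CORTICAL", 1), ("TRABECULAR", 0)):
            ids = np.where(fm.region == code)[0] + 1
            fh.write(f"*ELSET, ELSET={name}\n")
            for k in range(0, len(ids), 16):
                fh.write(", ".join(str(v) for v in ids[k:k + 16]) + "\n")


def write_surface_stl(path: PathLike, fm: FemurModel) -> None:
    """Surface triangulation as STL (binary) via trimesh."""
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=fm.nodes, faces=fm.surface_faces, process=False)
    mesh.export(str(path))


def morphologies_to_csv(path: PathLike,
                        morphologies: Iterable[MorphologySet],
                        ids: Optional[Sequence] = None) -> pd.DataFrame:
    """One row per femur, columns are the parameter abbreviations."""
    df = pd.DataFrame([m.as_dict() for m in morphologies],
                      columns=list(PARAMETER_NAMES))
    df.insert(0, "femur_id", list(ids) if ids is not None
              else np.arange(len(df)))
    df.to_csv(path, index=False)
    return df


def morphologies_from_csv(path: PathLike) -> list:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(MorphologySet(**{k: float(row[k])
                                    for k in PARAMETER_NAMES}))
    return out


def write_json(path: PathLike, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return json.loads(obj.to_json(orient="split"))
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
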