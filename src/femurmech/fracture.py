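"""Strain-based connected-volume fracture criterion.

A femur is considered fractured at the first load increment at which a
face-connected group of *cortical* elements, all exceeding the same
principal-strain limit (tensile 0.0073 or compressive 0.0104), reaches
a total volume of at least 100 mm³.  Because strains scale linearly
with the applied load, the exceedance sets grow monotonically with the
load and the first-crossing increment can be located by bisection over
the 100 N grid; the result is identical to an exhaustive scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc

from .errors import ConfigurationError
from .fe import ElementStrainField, MaterialAndCriterionConfig
from .meshing import REGION_CORTICAL

__all__ = ["FractureResult", "exceeding_components", "fracture_load"]

MODE_TENSILE = "tensile"
MODE_COMPRESSIVE = "compressive"
MODE_NONE = "none"


@dataclass(frozen=True)
class FractureResult:
    """Outcome of the incremental fracture search for one load case.

    ``load`` is the fracture load in N (a multiple of the increment) or
    ``None`` if no qualifying element group exists up to the maximum
    load.  ``tie`` flags that both limit types first qualified at the
    same increment (reported as compressive).
    """

    load: Optional[float]
    mode: str
    failing_elements: np.ndarray
    failing_volume: float
    case: str
    tie: bool = False

    @property
    def fractured(self) -> bool:
        return self.load is not None


@dataclass
class _Components:
    """Connected exceedance components of one mode at one load."""

    elements: List[np.ndarray] = field(default_factory=list)
    volumes: List[float] = field(default_factory=list)

    def max_volume(self) -> float:
        return max(self.volumes, default=0.0)


def _components_of(mask: np.ndarray, field_: ElementStrainField
                   ) -> _Components:
    out = _Components()
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return out
    pos = -np.ones(len(mask), dtype=np.int64)
    pos[idx] = np.arange(len(idx))
    adj = field_.adjacency
    sel = mask[adj[:, 0]] & mask[adj[:, 1]]
    pairs = adj[sel]
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pos[pairs[:, 0]], pos[pairs[:, 1]])),
        shape=(len(idx), len(idx)))
    n_comp, label = _cc(graph, directed=False)
    for c in range(n_comp):
        members = idx[label == c]
        out.elements.append(members)
        out.volumes.append(float(field_.volume[members].sum()))
    order = np.argsort(out.volumes)[::-1]
    out.elements = [out.elements[i] for i in order]
    out.volumes = [out.volumes[i] for i in order]
    return out


def exceeding_components(field_: ElementStrainField, F: float,
                         cfg: MaterialAndCriterionConfig
                         ) -> Dict[str, _Components]:
    """Face-connected cortical exceedance components per mode at load F.

    Components are sorted by volume, largest first.  Trabecular elements
    never participate (the criterion addresses the cortical shell only).
    """
    if F <= 0:
        raise ConfigurationError("load must be positive")
    e_max, e_min = field_.at_load(F)
    cortical = field_.region == REGION_CORTICAL
    tens = cortical & (e_max > cfg.eps_tensile)
    comp = cortical & (e_min < -cfg.eps_compressive)
    return {
        MODE_TENSILE: _components_of(tens, field_),
        MODE_COMPRESSIVE: _components_of(comp, field_),
    }


def _qualifies(field_: ElementStrainField, F: float,
               cfg: MaterialAndCriterionConfig) -> Dict[str, _Components]:
    comps = exceeding_components(field_, F, cfg)
    return {mode: c for mode, c in comps.items()
            if c.max_volume() >= cfg.V_crit}


def fracture_load(field_: ElementStrainField,
                  cfg: Optional[MaterialAndCriterionConfig] = None
                  ) -> FractureResult:
    """First load increment with a qualifying exceedance component.

    Bisection over the increment grid {dF, 2 dF, …, F_max}; valid
    because exceedance sets only grow with the load.  A tie between the
    two modes at the same increment is reported as compressive.
    """
    cfg = cfg or MaterialAndCriterionConfig()
    cfg.validate()
    n_steps = int(round(cfg.F_max / cfg.dF))
    lo, hi = 1, n_steps            # in units of dF
    if not _qualifies(field_, n_steps * cfg.dF, cfg):
        return FractureResult(load=None, mode=MODE_NONE,
                              failing_elements=np.empty(0, dtype=np.int64),
                              failing_volume=0.0, case=field_.case)
    while lo < hi:
        mid = (lo + hi) // 2
        if _qualifies(field_, mid * cfg.dF, cfg):
            hi = mid
        else:
            lo = mid + 1
    F = lo * cfg.dF
    qual = _qualifies(field_, F, cfg)
    tie = len(qual) == 2
    if MODE_COMPRESSIVE in qual:
        mode = MODE_COMPRESSIVE
    else:
        mode = MODE_TENSILE
    comp = qual[mode]
    return FractureResult(load=float(F), mode=mode,
                          failing_elements=comp.elements[0],
                          failing_volume=comp.volumes[0],
                          case=field_.case, tie=tie)
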