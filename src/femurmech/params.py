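"""Morphological parameter sets and the cohort sampling model.

Sixteen scalar parameters describe one femur.  Twelve of them are free
inputs of the parametric construction and are drawn from independent
truncated normal distributions calibrated to published cohort statistics
(mean, SD, observed minimum/maximum of 20 adult femurs).  The remaining
four (``OSA``, ``OSH``, ``NCDF``, ``NCDS``) are geometric consequences of
the construction and are derived in closed form so that every sampled set
is self-consistent (e.g. ``OSH = FNAL * sin(NSA)`` up to the small
head-centre offset).

Axis convention (right femur, canonical frame): x points lateral→medial,
y posterior→anterior, z distal→proximal.  All lengths in mm, angles in
degrees.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
from scipy import stats as _stats

from .errors import ConfigurationError, EmptyRequestError

__all__ = [
    "PARAMETER_NAMES",
    "SAMPLED_PARAMETERS",
    "DERIVED_PARAMETERS",
    "DEFAULT_CALIBRATION",
    "ParamCalibration",
    "MorphologySet",
    "GeneratorConfig",
    "sample_morphologies",
    "derive_dependent_parameters",
    "neck_axis_direction",
]

#: All sixteen parameter abbreviations, alphabetical as conventionally tabulated.
PARAMETER_NAMES: Tuple[str, ...] = (
    "ATA", "aMSA", "BA", "DCHD", "DCVD", "FHD", "FNAL", "GTH",
    "NCDF", "NCDS", "ND", "NSA", "OSA", "OSH", "OSV", "TFL",
)

#: Parameters drawn independently; the rest follow from the construction.
SAMPLED_PARAMETERS: Tuple[str, ...] = (
    "ATA", "aMSA", "BA", "DCHD", "DCVD", "FHD", "FNAL", "GTH",
    "ND", "NSA", "OSV", "TFL",
)

DERIVED_PARAMETERS: Tuple[str, ...] = ("NCDF", "NCDS", "OSA", "OSH")

_ANGLES = ("ATA", "aMSA", "BA", "NSA")


@dataclass(frozen=True)
class ParamCalibration:
    """Truncated-normal calibration of one parameter: N(mean, sd) on [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: SD must be >= 0, got {self.sd}")
        if not self.lo < self.hi:
            raise ConfigurationError(
                f"{name}: truncation bounds must satisfy lo < hi, "
                f"got [{self.lo}, {self.hi}]"
            )


#: Cohort descriptive statistics (mean, SD, min, max) used as sampling targets.
DEFAULT_CALIBRATION: Dict[str, ParamCalibration] = {
    "ATA": ParamCalibration(10.26, 5.64, 1.99, 24.44),
    "aMSA": ParamCalibration(5.24, 1.31, 3.27, 8.78),
    "BA": ParamCalibration(11.19, 2.62, 4.44, 15.75),
    "DCHD": ParamCalibration(1.13, 1.98, -3.75, 5.11),
    "DCVD": ParamCalibration(-0.19, 1.26, -1.68, 2.25),
    "FHD": ParamCalibration(48.74, 4.04, 42.48, 55.76),
    "FNAL": ParamCalibration(51.90, 7.23, 36.05, 64.15),
    "GTH": ParamCalibration(7.89, 5.01, -0.27, 17.57),
    "NCDF": ParamCalibration(2.00, 0.93, 0.54, 4.40),
    "NCDS": ParamCalibration(2.12, 0.89, 0.67, 4.37),
    "ND": ParamCalibration(38.02, 3.35, 32.11, 44.83),
    "NSA": ParamCalibration(124.84, 4.56, 115.15, 134.62),
    "OSA": ParamCalibration(45.71, 6.41, 30.49, 59.12),
    "OSH": ParamCalibration(41.85, 7.09, 27.47, 58.53),
    "OSV": ParamCalibration(59.31, 5.68, 49.41, 71.37),
    "TFL": ParamCalibration(468.44, 37.71, 396.42, 531.31),
}


@dataclass(frozen=True)
class MorphologySet:
    """The sixteen morphological parameters of one femur.

    Angles in degrees, lengths in mm.  ``DCHD``, ``DCVD`` and ``GTH`` are
    signed; the remaining lengths are non-negative.
    """

    ATA: float
    aMSA: float
    BA: float
    DCHD: float
    DCVD: float
    FHD: float
    FNAL: float
    GTH: float
    NCDF: float
    NCDS: float
    ND: float
    NSA: float
    OSA: float
    OSH: float
    OSV: float
    TFL: float

    def __post_init__(self) -> None:
        for name in ("FHD", "FNAL", "ND", "TFL", "OSA", "OSH", "OSV"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("NCDF", "NCDS"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 90.0 < self.NSA < 180.0:
            raise ConfigurationError("NSA must lie in (90, 180) degrees")
        if self.OSH > self.OSA + 1e-9:
            raise ConfigurationError("OSH cannot exceed OSA (frontal projection)")
        if self.TFL <= self.OSV:
            raise ConfigurationError("TFL must exceed OSV")

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES])


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic femur generator.

    Parameters
    ----------
    calibration
        Per-parameter truncated-normal calibration.  Only the entries for
        :data:`SAMPLED_PARAMETERS` are sampled; entries for derived
        parameters are kept for reference/reporting.
    cohort_size
        Number of femurs per cohort.
    seed
        Seed of the deterministic random stream.
    edge_length
        Target mean edge length of the tetrahedral mesh in mm.
    cortical_thickness
        Cortical shell thickness (mm) per anatomical region, before scaling.
    thickness_scale
        Single global multiplier on all cortical thicknesses.  This is the
        one mechanics-calibration knob of the generator; its default was
        fixed once against the published cohort-mean sideways-fall strength
        and is not meant to be tuned per run.
    """

    calibration: Dict[str, ParamCalibration] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    cohort_size: int = 20
    seed: int = 0
    edge_length: float = 2.5
    cortical_thickness: Dict[str, float] = field(
        default_factory=lambda: {"shaft": 6.0, "trochanter": 3.0, "neck": 2.0, "head": 1.5}
    )
    #: frozen mechanics calibration (cohort-mean sideways-fall strength)
    thickness_scale: float = 0.70
    #: radial gap (mm) below which separate cross-section parts are bridged
    merge_gap: float = 10.0
    #: reference cross-section radius (mm) used to pick angular/radial counts
    reference_radius: float = 16.0

    def validate(self) -> None:
        for name in SAMPLED_PARAMETERS:
            if name not in self.calibration:
                raise ConfigurationError(f"calibration missing parameter {name}")
            self.calibration[name].validate(name)
        if self.edge_length <= 0:
            raise ConfigurationError("edge_length must be positive")
        if self.thickness_scale <= 0:
            raise ConfigurationError("thickness_scale must be positive")
        if any(t <= 0 for t in self.cortical_thickness.values()):
            raise ConfigurationError("cortical thicknesses must be positive")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def neck_axis_direction(nsa_deg: float, ata_deg: float) -> np.ndarray:
    """Unit neck-axis direction from shaft-neck angle and antetorsion.

    Built so that the *frontal-plane projection* of the axis makes
    ``180 - NSA`` degrees with the proximal shaft direction (+z) and the
    transversal projection makes ``ATA`` degrees with the condylar (+x)
    axis, matching how both angles are measured.
    """
    alpha = math.radians(180.0 - nsa_deg)
    ata = math.radians(ata_deg)
    v = np.array([math.sin(alpha), math.sin(alpha) * math.tan(ata), math.cos(alpha)])
    return v / np.linalg.norm(v)


def head_centre_offset(m_sampled: Dict[str, float]) -> np.ndarray:
    """Offset ``d`` of the head centre from the neck axis (perpendicular).

    ``d_y = DCHD`` (anterior), ``d_z = DCVD`` (cranial); ``d_x`` follows
    from ``d ⟂ n``.
    """
    n = neck_axis_direction(m_sampled["NSA"], m_sampled["ATA"])
    dy = m_sampled["DCHD"]
    dz = m_sampled["DCVD"]
    dx = -(dy * n[1] + dz * n[2]) / n[0]
    return np.array([dx, dy, dz])


def derive_dependent_parameters(m_sampled: Dict[str, float]) -> Dict[str, float]:
    """Closed-form OSA/OSH/NCDF/NCDS for a sampled construction set.

    With the neck-shaft intersection at the origin and the shaft axis along
    z, the head centre is ``FHC = FNAL*n + d``; the four derived distances
    follow directly.
    """
    n = neck_axis_direction(m_sampled["NSA"], m_sampled["ATA"])
    d = head_centre_offset(m_sampled)
    fhc = m_sampled["FNAL"] * n + d
    return {
        "OSH": float(abs(fhc[0])),
        "OSA": float(math.hypot(fhc[0], fhc[1])),
        "NCDF": float(math.hypot(d[0], d[2])),
        "NCDS": float(math.hypot(d[1], d[2])),
    }


def _draw_truncated_normal(
    cal: ParamCalibration, size: int, rng: np.random.Generator
) -> np.ndarray:
    if cal.sd == 0.0:
        return np.full(size, cal.mean)
    a = (cal.lo - cal.mean) / cal.sd
    b = (cal.hi - cal.mean) / cal.sd
    return _stats.truncnorm.rvs(a, b, loc=cal.mean, scale=cal.sd,
                                size=size, random_state=rng)


def sample_morphologies(config: GeneratorConfig) -> List[MorphologySet]:
    """Draw a cohort of morphological parameter sets.

    Independent truncated-normal draws for the twelve construction
    parameters; ``OSA``, ``OSH``, ``NCDF`` and ``NCDS`` are derived from the
    construction geometry.  Identical ``config`` (including seed) yields an
    identical cohort.
    """
    config.validate()
    if config.cohort_size < 1:
        raise EmptyRequestError(
            f"cohort_size must be >= 1, got {config.cohort_size}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.cohort_size
    draws = {
        name: _draw_truncated_normal(config.calibration[name], n, rng)
        for name in SAMPLED_PARAMETERS
    }
    out: List[MorphologySet] = []
    for i in range(n):
        sampled = {name: float(draws[name][i]) for name in SAMPLED_PARAMETERS}
        derived = derive_dependent_parameters(sampled)
        out.append(MorphologySet(**sampled, **derived))
    return out


def cohort_frame(morphologies: Iterable[MorphologySet]):
    """Morphologies as a pandas DataFrame, one row per femur."""
    import pandas as pd

    rows = [m.as_dict() for m in morphologies]
    return pd.DataFrame(rows, columns=list(PARAMETER_NAMES))
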