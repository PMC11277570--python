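"""Exception hierarchy for femurmech."""


class FemurMechError(Exception):
    """Base class for all femurmech errors."""


class ConfigurationError(FemurMechError):
    """Invalid generator, material, or run configuration."""


class EmptyRequestError(ConfigurationError):
    """A cohort of fewer than one femur was requested."""


class ConstructionError(FemurMechError):
    """A morphology combination cannot be turned into a valid solid."""


class DegenerateGeometryError(FemurMechError):
    """An operation hit geometry it cannot work with (e.g. empty cut)."""


class SingularFitError(FemurMechError):
    """Least-squares landmark fit is singular (degenerate input points)."""


class FitConvergenceError(FemurMechError):
    """Iterative axis fit failed to converge."""


class LandmarkError(FemurMechError):
    """A required landmark or tagged region is missing from the mesh."""


class PatchSelectionError(FemurMechError):
    """A boundary-condition patch (load cap, trochanter support) is empty."""


class AssemblyError(FemurMechError):
    """Finite-element system could not be assembled or factorised."""


class RigidBodyModeError(AssemblyError):
    """The constrained stiffness matrix is singular (free rigid-body mode)."""


class UndefinedStatisticError(FemurMechError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
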