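"""Exception hierarchy shared across the package."""


class JawFEMError(Exception):
    """Base class for all package errors."""


class ParameterError(JawFEMError, ValueError):
    """Invalid user-supplied parameter (dimension, count, ratio...)."""


class GenerationError(JawFEMError, RuntimeError):
    """Synthetic geometry could not be generated (degenerate solid, empty label)."""


class SelectionError(JawFEMError, ValueError):
    """A node-set selection request cannot be satisfied."""


class MeshAuditError(JawFEMError, RuntimeError):
    """A generated mesh violates a structural invariant."""


class GeometryError(JawFEMError, RuntimeError):
    """Degenerate or inverted element encountered during FE assembly."""


class AssemblyError(JawFEMError, RuntimeError):
    """Global stiffness assembly failed (e.g. unmapped element)."""


class SolverError(JawFEMError, RuntimeError):
    """Constrained linear system is singular or ill-conditioned."""


class DistributionError(JawFEMError, RuntimeError):
    """Muscle traction cannot be distributed (zero patch area)."""


class ConfigError(JawFEMError, ValueError):
    """Run configuration violates the schema."""
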