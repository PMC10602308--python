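"""Exception hierarchy.

Parse problems carry row/column provenance so a user can fix the offending
line of a probe or relation table without guessing.
"""


class PhosphowalkError(Exception):
    """Base class for all package errors."""


class FormatError(PhosphowalkError, ValueError):
    """A table is structurally malformed (missing column, bad token)."""


class TableValidationError(PhosphowalkError, ValueError):
    """A table is well-formed but violates an invariant (duplicate id, negative signal)."""


class UndefinedValueError(PhosphowalkError, ArithmeticError):
    """A derived quantity (CFC, log2 fold change) is undefined for the inputs."""


class AmbiguousProbeError(PhosphowalkError, ValueError):
    """Two retained probes map to the same (substrate, site)."""


class RootlessNetworkError(PhosphowalkError, RuntimeError):
    """A walk was requested on a network with no in-degree-0 start node."""


class PlantingError(PhosphowalkError, RuntimeError):
    """No path satisfying the planted-cascade constraints exists."""


class ParameterError(PhosphowalkError, ValueError):
    """An operation was called with out-of-range parameters."""


class NotApplicableError(PhosphowalkError, ValueError):
    """A rule was invoked in a situation it does not cover."""
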