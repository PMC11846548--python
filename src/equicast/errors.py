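"""Exception hierarchy for equicast.

Every error raised deliberately by the package derives from
:class:`EquicastError`, so callers can catch the whole family at once.
"""


class EquicastError(Exception):
    """Base class for all equicast errors."""


class SchemaError(EquicastError):
    """A required column is missing or the header cannot be resolved."""


class PanelIntegrityError(EquicastError):
    """Row-level validation failed (duplicates, invariant violations)."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class DomainError(EquicastError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateInputError(EquicastError, ValueError):
    """Input is structurally valid but degenerate (all-zero, constant...)."""


class LengthError(EquicastError, ValueError):
    """A series is too short for the requested operation."""


class GroupingError(EquicastError, ValueError):
    """A region is unassigned or a grouping map is inconsistent."""


class FitError(EquicastError, RuntimeError):
    """An estimator failed to converge or produce a usable fit."""


class SelectionError(FitError):
    """Model selection found no candidate that could be fitted."""

    def __init__(self, message: str, failures: dict | None = None):
        super().__init__(message)
        self.failures = failures or {}
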