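"""Exception hierarchy used across the package."""


class MechanocaError(Exception):
    """Base class for all package errors."""


class DomainError(MechanocaError, ValueError):
    """A state variable left its physical domain (e.g. non-positive concentration)."""


class ConfigurationError(MechanocaError, ValueError):
    """Inconsistent model/run configuration (e.g. resting flux balance violated)."""


class PreconditionError(MechanocaError, ValueError):
    """An operation was called on inputs that violate its contract."""


class DataError(MechanocaError, ValueError):
    """Malformed or unusable input data."""


class SchemaError(DataError):
    """A table is missing required columns or has the wrong layout."""


class NumericalError(MechanocaError, RuntimeError):
    """The numerical integrator failed."""


class FitError(MechanocaError, RuntimeError):
    """No optimization start converged."""


class SweepError(MechanocaError, RuntimeError):
    """A perturbation sweep failed or was queried outside its range."""
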