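"""Exception hierarchy.

Every error raised by the package derives from :class:`HairEtgError` so callers
(and the CLI) can distinguish analytical failures from programming errors.
"""


class HairEtgError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(HairEtgError, ValueError):
    """A simulation spec violates an invariant; the message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid spec field '{field}': {message}")


class WindowError(HairEtgError, ValueError):
    """An integration or noise window falls outside the trace time range."""


class ResolutionError(HairEtgError, ValueError):
    """A window contains too few samples for the requested operation."""


class ContaminationError(HairEtgError, ValueError):
    """A noise-estimation region overlaps a declared chromatographic peak."""


class InsufficientDataError(HairEtgError, ValueError):
    """Not enough points / levels / replicates for the requested statistic."""


class DesignError(HairEtgError, ValueError):
    """A factorial design table is incomplete or inconsistent."""


class ConfigurationError(HairEtgError, ValueError):
    """Mutually inconsistent or out-of-range configuration values."""


class FixtureError(HairEtgError, KeyError):
    """Unknown packaged fixture name."""
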