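"""Exception hierarchy. The CLI maps these to distinct exit codes."""


class CephGrowthError(Exception):
    """Base class for package errors."""


class ConfigurationError(CephGrowthError):
    """An invalid configuration value; the message names the field."""


class DataError(CephGrowthError):
    """Malformed, incomplete or inconsistent input data."""


class DegenerateGeometryError(CephGrowthError):
    """A geometric construction is undefined (coincident points, zero-length line)."""


class NumericalError(CephGrowthError):
    """A numerical procedure failed (divergent training, non-finite loss)."""
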