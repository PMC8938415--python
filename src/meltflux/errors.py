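"""Exception hierarchy.

All errors raised by the package derive from :class:`MeltfluxError` so callers
can catch everything from one place.  Subclasses separate configuration
mistakes (bad knob values), format problems (a file that cannot be read as
the documented CSV dialect), integrity violations (duplicate keys, mismatched
tables) and statistically degenerate inputs.
"""


class MeltfluxError(Exception):
    """Base class for all package errors."""


class ConfigError(MeltfluxError, ValueError):
    """A configuration value is invalid; the message names the field."""


class FormatError(MeltfluxError, ValueError):
    """An input file does not follow the expected CSV dialect."""


class IntegrityError(MeltfluxError, ValueError):
    """Keyed data violates a uniqueness or cross-table consistency contract."""


class InsufficientDataError(MeltfluxError, ValueError):
    """Too few complete cases to compute the requested statistic."""


class DegenerateInputError(MeltfluxError, ValueError):
    """Input is constant, empty, or otherwise statistically degenerate."""
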