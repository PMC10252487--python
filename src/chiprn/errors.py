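"""Exception hierarchy.

Config problems (bad parameters, bad YAML schema) and data problems (bad
files, bad coordinates, wrong normalization state) are kept in separate
branches so the CLI can map them to distinct exit codes (2 and 3).
"""


class ChipRnError(Exception):
    """Base class for all package errors."""


class ConfigError(ChipRnError):
    """Invalid parameter value or configuration."""


class SchemaError(ConfigError):
    """YAML run-config does not validate; message names the field path."""


class DataError(ChipRnError):
    """Base class for input-data problems."""


class FormatError(DataError):
    """A file does not conform to its declared dialect."""


class CoordinateError(DataError):
    """Coordinates outside the assembly, or an unknown chromosome."""


class StateError(DataError):
    """A track is in the wrong normalization state for the operation."""


class DegenerateInputError(DataError):
    """Numerically degenerate input (zero totals, zero background, ...)."""
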