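"""Exception hierarchy.

Exit codes follow the CLI contract: 0 ok, 2 configuration error, 3 data error.
"""


class RejuvkitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(RejuvkitError):
    """Invalid parameters, specs, or config files."""

    exit_code = 2


class FormatError(ConfigurationError):
    """Malformed input file (bad header, duplicate ids, out-of-range cell)."""


class DataError(RejuvkitError):
    """Inputs are well-formed but unusable (too few samples, no shared features)."""

    exit_code = 3


class CoverageError(DataError):
    """Too few model features present in the query matrix."""


class SelectionError(DataError):
    """A feature-selection step returned an empty set."""


class PlacementError(DataError):
    """Could not place synthetic objects without overlap."""


class EdgeNotFoundError(DataError):
    """No image column reached the coverage threshold for edge detection."""
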