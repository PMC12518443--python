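"""Exception hierarchy shared across the package.

Data errors (bad files, bad geometry) and usage errors (wrong call order,
unknown options) are kept distinct so the CLI can map them to exit codes
1 and 2 respectively.
"""


class TablesideError(Exception):
    """Base class for all package errors."""


class DataError(TablesideError):
    """Input data is malformed or inconsistent (CLI exit code 1)."""


class FormatError(DataError):
    """A file does not conform to its declared dialect or schema."""


class GeometryError(DataError):
    """A region polygon is unusable (e.g. fewer than 3 vertices)."""


class ConfigurationError(DataError):
    """A configuration table is incomplete (e.g. unmapped activity label)."""


class UsageError(TablesideError):
    """The caller violated a precondition (CLI exit code 2)."""


class UndefinedMetricError(TablesideError):
    """A metric was requested on an empty pose set: 0/0 is undefined, not 0."""
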