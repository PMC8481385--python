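"""Exception hierarchy.

All hard errors raised by the library derive from :class:`ClinenrichError`
so the CLI can map them to distinct exit codes.
"""


class ClinenrichError(Exception):
    """Base class for all clinenrich errors."""


class ValidationError(ClinenrichError):
    """Input data violates a structural contract (duplicate IDs, bad types...)."""


class InputFormatError(ClinenrichError):
    """A file could not be parsed into the expected shape."""


class SelectionError(ClinenrichError):
    """A subcohort selection request cannot be satisfied."""
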