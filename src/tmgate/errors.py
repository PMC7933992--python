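"""Exception hierarchy.

All package errors derive from :class:`TmgateError` so callers (and the CLI)
can distinguish configuration, input-data and file-format problems.
"""


class TmgateError(Exception):
    """Base class for all tmgate errors."""


class ConfigError(TmgateError):
    """A parameter object or pipeline configuration is invalid."""


class InputError(TmgateError):
    """Input data violates a contract (duplicate barcodes, missing labels...)."""


class FormatError(TmgateError):
    """A file does not conform to its declared format."""
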