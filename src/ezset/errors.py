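"""Exception hierarchy.

``ValidationError`` covers malformed inputs (CLI exit code 1);
``EzsetError`` subclasses raised during computation map to exit code 2.
"""


class EzsetError(Exception):
    """Base class for all package errors."""


class ValidationError(EzsetError):
    """Input data or configuration violates the documented schema."""


class DegeneratePanelError(EzsetError):
    """A panel with no usable borderline interval (zero dispersion, zero gap)."""
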