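"""Exception hierarchy.

All user-facing errors derive from :class:`MirtrajError` so callers (and the
CLI) can distinguish bad inputs from bugs.
"""


class MirtrajError(Exception):
    """Base class for all mirtraj errors."""


class FormatError(MirtrajError, ValueError):
    """A file could not be parsed (bad header, non-numeric cell, ...)."""


class ValidationError(MirtrajError, ValueError):
    """Parsed data violate an invariant (duplicate IDs, unknown labels, ...)."""


class DegenerateDataError(MirtrajError, ValueError):
    """Data carry no usable variance (e.g. all-identical vectors fed to PCA)."""


class UndefinedDirectionError(MirtrajError, ValueError):
    """A direction was requested between two coincident points."""
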