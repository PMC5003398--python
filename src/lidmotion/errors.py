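"""Exception hierarchy.

Every error raised by this package derives from :class:`LidmotionError`,
so callers (and the CLI) can map failures onto coarse categories:
validation of inputs, file I/O / format problems, and computation errors.
"""


class LidmotionError(Exception):
    """Base class for all lidmotion errors."""


class ValidationError(LidmotionError):
    """Invalid parameters, topology ranges, or restraint definitions."""


class FormatError(LidmotionError):
    """A file exists but does not conform to the expected format."""


class GeometryError(LidmotionError):
    """Degenerate or insufficient geometry (too few points, collinear sets...)."""


class TopologyError(LidmotionError):
    """A required topology field (hinge set, axis reference...) is missing."""


class SelectionError(LidmotionError):
    """An atom/residue selection is empty or ill-formed."""


class CorrespondenceError(LidmotionError):
    """No common residues between two structures."""


class ResidueLookupError(LidmotionError):
    """A named residue or atom is absent from a structure."""


class MissingDataUndeterminableError(LidmotionError):
    """Missing-residue bookkeeping was requested but the file carries neither
    unresolved-residue remarks nor a usable full-sequence record."""


class InsufficientDataError(LidmotionError):
    """Not enough frames/observations for the requested analysis."""


class ConfigurationError(LidmotionError):
    """Inconsistent analysis configuration (e.g. restraints within one domain)."""
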