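"""Exception hierarchy for paralogmeth.

All package-specific errors derive from :class:`ParalogMethError` so callers
can catch one base class at the CLI boundary.
"""


class ParalogMethError(Exception):
    """Base class for all paralogmeth errors."""


class SequenceError(ParalogMethError, ValueError):
    """Malformed nucleotide sequence or genomic region."""


class PatternError(SequenceError):
    """Methylation pattern inconsistent with the sequence it refers to."""


class AmpliconNotFoundError(ParalogMethError):
    """No PCR product could be predicted for a primer pair on a template."""


class AssayConfigError(ParalogMethError, ValueError):
    """Assay configuration is malformed or internally inconsistent."""


class StallError(AssayConfigError):
    """A dispensation order fails to consume the full sequencing window."""


class UndefinedSignalError(ParalogMethError):
    """Peak fraction requested where variant + reference signal is zero."""


class DeconvolutionError(ParalogMethError):
    """Paralog deconvolution is impossible (no marker signal / zero proportion)."""


class CalibrationError(ParalogMethError):
    """HRM normalization or calibration cannot be computed."""


class ParseError(ParalogMethError, ValueError):
    """A file could not be parsed; message carries the offending line."""
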