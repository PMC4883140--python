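"""Exception hierarchy shared across the package."""


class SmartTraceError(Exception):
    """Base class for all package-specific errors."""


class SwcParseError(SmartTraceError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(SmartTraceError):
    """An SWC file parsed but describes an invalid tree (dangling parent, cycle...)."""


class ImageFormatError(SmartTraceError):
    """An image file is not a grayscale integer stack and no conversion was requested."""


class PhantomSpecError(SmartTraceError):
    """A synthetic-volume specification is internally inconsistent or out of bounds."""


class InsufficientExemplarsError(SmartTraceError):
    """No confident segments (or an empty sample class) — training cannot proceed.

    This is the observed failure mode of self-supervised tracing on images whose
    initial reconstruction is too poor to yield reliable exemplars.  Callers may
    retry with a relaxed confidence threshold, a different initial tracer, or an
    additional iteration round.
    """
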