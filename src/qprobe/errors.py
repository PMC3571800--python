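"""Exception types shared across the package."""


class QProbeError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(QProbeError, ValueError):
    """A sequence contains characters outside uppercase A/C/G/T."""


class AlignmentError(QProbeError, ValueError):
    """No probe footprint on the target satisfies the mismatch budget."""


class DesignInfeasibleError(QProbeError, ValueError):
    """No assay component satisfies the stated design constraints.

    The message names the violated constraint so callers can relax it.
    """


class CatalogError(QProbeError, KeyError):
    """Unknown fixture locus; the message lists valid catalog ids."""


class ParseError(QProbeError, ValueError):
    """A file could not be parsed; the message carries the line number."""
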