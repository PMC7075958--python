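"""Exception hierarchy shared across the package."""


class MHFError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MHFError, ValueError):
    """A variant token or input table row could not be interpreted."""


class CoordinateError(MHFError, ValueError):
    """A residue coordinate falls outside its analysis region or sequence."""


class DomainOverlapError(MHFError, ValueError):
    """Two domain annotations overlap within one analysis."""


class ReferenceMismatchError(MHFError, ValueError):
    """A variant's stated reference residue disagrees with the sequence."""


class EmptySetError(MHFError, ValueError):
    """The filtered mutation set is empty; the hotspot test refuses to run."""


class ProtocolError(MHFError, ValueError):
    """Two recordings that must share a voltage protocol do not."""


class FitError(MHFError, RuntimeError):
    """A curve fit failed to converge or the data cannot support it."""
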