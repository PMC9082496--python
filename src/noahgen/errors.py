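"""Exception hierarchy for noahgen.

Every error raised deliberately by the library derives from :class:`NoahError`
so that the CLI can map them onto stable exit codes.
"""


class NoahError(Exception):
    """Base class for all noahgen errors."""


class UnknownModule(NoahError):
    """Requested module abbreviation is not in the registry."""


class UnknownVariant(NoahError):
    """Requested variant label does not exist for the module."""


class NonPositiveCoupling(NoahError):
    """A scalar coupling constant must be strictly positive."""


class HMBCNotPresent(NoahError):
    """zz-filter resolution was requested for a sequence without an HMBC module."""


class NotSeHSQC(NoahError):
    """ZIP resolution was requested at a position that is not a seHSQC module."""


class NotViable(NoahError):
    """Supersequence failed viability checking outside developer mode."""


class ParameterConflict(NoahError):
    """Two modules define the same parameter slot with different meanings."""


class PhaseIndexConflict(NoahError):
    """Two modules define the same ph# index with different step lists."""


class MalformedFooter(NoahError):
    """Pulse program footer is missing or cannot be parsed."""


class SectionOrderError(NoahError):
    """The nine pulse-program sections are missing or out of order."""


class MissingAnnotation(NoahError):
    """A parameter lacks the one-line description required for the ased screen."""


class UnknownFlag(NoahError):
    """Acquisition flag symbol is not one of the supported zgoptns symbols."""


class BadFraction(NoahError):
    """NUS sampling fraction must lie in (0, 1]."""
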