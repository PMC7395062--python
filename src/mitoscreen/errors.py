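"""Exception hierarchy shared across the package."""


class MitoscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MitoscreenError):
    """A file or table does not have the expected structure."""


class ValidationError(MitoscreenError):
    """Structurally valid input violates a domain constraint."""


class DomainError(MitoscreenError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ScheduleError(MitoscreenError):
    """Injection-phase labels do not match the declared schedule."""


class DegenerateWellError(MitoscreenError):
    """A well cannot be normalized (e.g. zero baseline signal)."""


class DegeneratePlateError(MitoscreenError):
    """A plate-level reference quantity is unusable."""
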