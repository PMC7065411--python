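"""Exception hierarchy for the cowbw package."""


class CowbwError(Exception):
    """Base class for all package errors."""


class InputError(CowbwError):
    """Invalid user-supplied value (unknown class label, missing trait, ...)."""


class DomainError(CowbwError):
    """A day relative to calving outside the supported range."""


class ConfigError(CowbwError):
    """Invalid or infeasible simulation / pipeline configuration."""


class FitError(CowbwError):
    """Model estimation failed (empty fixed-effect class, non-convergence)."""
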