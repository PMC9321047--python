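"""Exception hierarchy for the foci package."""


class FociError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FociError, ValueError):
    """A tabular input file does not have the expected layout (e.g. a
    required column is missing or unresolvable)."""


class ValidationError(FociError, ValueError):
    """Input values violate a documented invariant or precondition
    (non-increasing times, duplicate frames, too few observations, ...)."""
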