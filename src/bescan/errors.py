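"""Exception types shared across the toolkit."""


class BescanError(Exception):
    """Base class for all toolkit errors."""


class FormatError(BescanError):
    """A table or sequence file violates the expected format."""


class TargetNotFoundError(BescanError):
    """Protospacer has no PAM-adjacent match in the locus."""


class AmbiguousTargetError(BescanError):
    """Protospacer matches the locus at more than one PAM-adjacent site."""

    def __init__(self, message: str, sites=None):
        super().__init__(message)
        self.sites = list(sites or [])


class DegenerateDistributionError(BescanError):
    """A score distribution has zero spread and cannot be standardized."""
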