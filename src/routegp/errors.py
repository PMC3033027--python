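"""Exception hierarchy for routegp."""


class RouteGPError(Exception):
    """Base class for all routegp errors."""


class ParseError(RouteGPError):
    """A track file could not be parsed; the message names the offending line."""


class ValidationError(RouteGPError, ValueError):
    """Input data violates a structural invariant (duplicate timestamps, bad ranges...)."""


class DegenerateTrackError(RouteGPError):
    """A track collapsed to fewer than two usable samples."""


class DomainError(RouteGPError, ValueError):
    """An argument lies outside its mathematical domain (e.g. normalized time not in [0,1])."""


class NumericalError(RouteGPError):
    """A covariance matrix failed Cholesky factorization even after jitter escalation."""


class MixingError(RouteGPError):
    """An MCMC chain accepted no moves after burn-in; step size or prior needs review."""
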