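"""Exception types for regime and configuration failures."""

from __future__ import annotations


class EcnleError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EcnleError, ValueError):
    """An input lies outside the physically valid domain."""


class NoCageError(EcnleError):
    """g(r) has no resolvable first minimum beyond the main peak.

    Raised at low volume fractions where the fluid is too weakly
    structured to define a particle cage.
    """

    def __init__(self, phi: float, message: str | None = None):
        self.phi = phi
        super().__init__(message or f"no cage minimum found in g(r) at phi={phi:g}")


class NoBarrierError(EcnleError):
    """The dynamic free energy has no interior minimum-maximum pair.

    The fluid is not dynamically arrested at this state point; carries
    the (phi, pstar) at which the landscape was evaluated.
    """

    def __init__(self, phi: float, pstar: float, message: str | None = None):
        self.phi = phi
        self.pstar = pstar
        super().__init__(
            message
            or f"no activation barrier at phi={phi:g}, pstar={pstar:g} (fluid regime)"
        )


class ConfigurationError(EcnleError):
    """A material model is missing a parameter required for the requested mode."""


class RangeError(EcnleError):
    """A solver target lies outside the reachable range of the scanned window."""


class FitError(EcnleError):
    """Parameter fitting failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
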