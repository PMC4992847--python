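"""Exception types raised by sepx."""


class SepxError(Exception):
    """Base class for all sepx errors."""


class DimensionMismatchError(SepxError, ValueError):
    """State vector length does not match the model dimension."""


class NonFiniteStateError(SepxError, ValueError):
    """A state vector contains NaN or Inf."""


class NoEquilibriumError(SepxError, RuntimeError):
    """No equilibrium found in the search window."""


class NoThresholdError(SepxError, RuntimeError):
    """No separatrix exists (e.g. QIF driven at or above rheobase)."""


class BracketError(SepxError, ValueError):
    """A bisection bracket does not straddle a classifier flip."""


class RegionAmbiguityError(SepxError, ValueError):
    """State sits exactly on a piecewise breakpoint and no region was given."""


class FixtureValidationError(SepxError, RuntimeError):
    """A built-in model fixture failed its self-check."""


class ConfigError(SepxError, ValueError):
    """Malformed or inconsistent run configuration."""


class IntegrationError(SepxError, RuntimeError):
    """The integrator produced a non-finite state."""
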