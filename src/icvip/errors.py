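"""Exception types shared across the package."""


class ICVipError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ICVipError, ValueError):
    """A generator or analysis configuration is invalid (non-finite or out of range)."""


class FormatError(ICVipError, ValueError):
    """An input file violates its format contract (SWC, sweep TSV, manifest)."""


class InsufficientDataError(ICVipError, ValueError):
    """Too few qualifying sweeps / spikes / samples for the requested estimate."""


class NotClassifiableError(ICVipError, ValueError):
    """No suprathreshold sweep: the firing pattern cannot be classified."""


class NoEventError(ICVipError, ValueError):
    """No synaptic event detected in a trace (no half-amplitude crossing)."""


class AnalysisError(ICVipError, RuntimeError):
    """A numerical analysis step failed (e.g. most exponential fits diverged)."""
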