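"""Exception types raised by the simulator."""


class CardioloopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardioloopError):
    """A spec, parameter file, or scenario violates a structural invariant."""


class IntegrationError(CardioloopError):
    """The numerical integration produced non-finite or unstable output."""
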