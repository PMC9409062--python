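"""Exception hierarchy shared by all pipeline stages."""


class PhagePipeError(Exception):
    """Base class for all phagepipe errors."""


class ParseError(PhagePipeError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PhagePipeError):
    """Parsed data violates a domain invariant (bounds, symmetry, ...)."""


class ConfigurationError(PhagePipeError):
    """A parameter or fixture specification is infeasible or inconsistent."""


class ContractError(PhagePipeError):
    """An operation was called outside its stated precondition."""


class StateError(PhagePipeError):
    """An object is not in the state an operation requires (e.g. tags unset)."""


class FeatureLookupError(PhagePipeError):
    """A referenced feature id is absent from the annotation."""


class UnsupportedOperationError(PhagePipeError):
    """The operation is undefined for this input (e.g. rotating a linear genome)."""
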