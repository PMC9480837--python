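"""Exception hierarchy."""


class VitaprofError(Exception):
    """Base class for all package errors."""


class ContractError(VitaprofError):
    """A precondition on an operation's inputs was violated."""


class ModelValidityError(VitaprofError):
    """A model is structurally unusable (e.g. no biomass objective)."""


class SolverStatusError(VitaprofError):
    """The LP solver returned an unusable status (e.g. unbounded)."""

    def __init__(self, message: str, status: str | None = None):
        super().__init__(message)
        self.status = status


class InfeasibleMediumError(VitaprofError):
    """A strain cannot reach the target growth on the supplied medium."""

    def __init__(self, message: str, strain_id: str | None = None):
        super().__init__(message)
        self.strain_id = strain_id


class AmbiguousGroupError(VitaprofError):
    """A strain matches more than one capability-group definition."""


class InternalConsistencyError(VitaprofError):
    """A result violates an internal invariant (essential ∩ optional ≠ ∅)."""
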