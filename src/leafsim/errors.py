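"""Exception hierarchy used across the package."""


class LeafSimError(Exception):
    """Base class for all leafsim errors."""


class InvalidInputError(LeafSimError, ValueError):
    """An argument violates a documented precondition."""


class SpecificationError(LeafSimError, ValueError):
    """A senescence specification is internally inconsistent."""


class ConfigurationError(LeafSimError, ValueError):
    """A simulation configuration cannot be satisfied (e.g. both endpoints
    of a violated spring are anchored)."""


class NumericalInstabilityError(LeafSimError, FloatingPointError):
    """The explicit integrator produced a non-finite quantity."""


class StageError(LeafSimError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
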