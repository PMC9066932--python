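"""Exception hierarchy.

All input-contract violations raise :class:`ValidationError`, so callers
(and the CLI) can distinguish bad data from programming errors.
"""


class CircDrugError(Exception):
    """Base class for all package errors."""


class ValidationError(CircDrugError, ValueError):
    """An input violated a documented precondition or invariant."""


class StructureParseError(ValidationError):
    """A molecular structure string could not be parsed."""


class TrainingDivergedError(CircDrugError):
    """Loss became non-finite during optimisation."""

    def __init__(self, epoch: int, message: str = ""):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
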