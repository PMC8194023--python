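"""Exception hierarchy shared across the package."""


class LonnrecError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LonnrecError, ValueError):
    """A numeric parameter violates its contract (e.g. beta = 0)."""


class InvalidInputError(LonnrecError, ValueError):
    """An input value violates its contract (e.g. non-finite x)."""


class ShapeError(LonnrecError, ValueError):
    """Dimension mismatch between data and a model or layer."""


class SchemaError(LonnrecError, ValueError):
    """A cohort table is missing columns or violates record invariants."""


class DivergenceError(LonnrecError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class SerializationError(LonnrecError, ValueError):
    """A model file could not be parsed or has an unsupported version."""
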