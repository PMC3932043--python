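"""Exception hierarchy shared across the pipeline stages."""


class BonemetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BonemetError):
    """A delimited input file is missing a mandatory column."""


class RowParseError(BonemetError):
    """A row of an input file could not be parsed (bad date, bad enum)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(f"row {row}: {message}" if row is not None else message)


class SpecConsistencyError(BonemetError):
    """A fixture specification violates its internal count constraints."""


class CrosstabInconsistencyError(BonemetError):
    """No integer 2x2 cell assignment reproduces the printed statistics."""


class CrosstabAmbiguityError(BonemetError):
    """More than one integer cell assignment reproduces the printed statistics."""

    def __init__(self, message: str, candidates: list | None = None):
        self.candidates = candidates or []
        super().__init__(message)


class StageError(BonemetError):
    """A pipeline stage failed; carries the stage name for the orchestrator."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
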