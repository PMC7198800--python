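"""Exception hierarchy shared across the package."""


class NitrofbaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NitrofbaError):
    """A domain object violates one of its structural invariants."""


class InputError(NitrofbaError):
    """User-supplied data or parameters are malformed or insufficient."""


class AlignmentError(InputError):
    """Time grids of plate-reader series cannot be aligned."""


class QuartileError(InputError):
    """Too few growth-positive wells to define intensity quartiles."""


class SolverError(NitrofbaError):
    """The LP/MILP backend failed for a reason other than infeasibility."""


class UngapfillableError(NitrofbaError):
    """No subset of the universal database enables growth on a condition."""

    def __init__(self, condition_id: str, message: str | None = None):
        self.condition_id = condition_id
        super().__init__(message or f"no gapfill enables growth on condition {condition_id!r}")


class StageError(NitrofbaError):
    """A pipeline stage is missing its inputs or failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
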