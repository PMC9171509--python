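"""Exception hierarchy."""


class LungAllocError(Exception):
    """Base class for package errors."""


class ValidationError(LungAllocError, ValueError):
    """Invalid input data: bad columns, duplicate ids, broken invariants."""


class AccountingError(LungAllocError, KeyError):
    """A centre referenced by a map or stream is missing from the activity table."""


class InfeasibleAssignmentError(LungAllocError):
    """No disjoint combination of candidate units exists.

    ``conflict`` names the smallest pair of LTC ids for which no
    disjoint candidate pair exists, when such a pair is identifiable.
    """

    def __init__(self, message: str, conflict: tuple[str, str] | None = None):
        super().__init__(message)
        self.conflict = conflict
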