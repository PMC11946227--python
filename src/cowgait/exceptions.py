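"""Exception hierarchy shared across the package."""


class CowgaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CowgaitError):
    """A keypoint table or label file does not match the documented dialect."""


class MissingKeypointError(FormatError):
    """One or more required keypoints are absent from a table.

    Carries the missing keypoint names in :attr:`missing`.
    """

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing keypoint columns: {', '.join(self.missing)}")


class ValidationError(CowgaitError):
    """A value violates a domain invariant (e.g. a grade outside 0..3)."""


class InsufficientDataError(CowgaitError):
    """Too few valid frames to produce a statistic or a score."""


class GenerationError(CowgaitError):
    """The synthetic-geometry solver cannot realize a requested angle."""
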