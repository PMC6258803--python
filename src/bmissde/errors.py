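"""Exception hierarchy for bmissde.

All anticipated user-facing failures derive from :class:`BmissdeError` so the
CLI can map them to a single exit code (2) while genuine bugs still raise
ordinary Python exceptions.
"""


class BmissdeError(Exception):
    """Base class for all bmissde errors."""


class ValidationError(BmissdeError, ValueError):
    """An input value violates a documented precondition.

    The message always names the offending field or argument.
    """


class SchemaError(BmissdeError, ValueError):
    """A tabular input does not conform to the cohort CSV schema."""


class CalibrationError(BmissdeError, RuntimeError):
    """A calibration search failed to reach its target within tolerance."""
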