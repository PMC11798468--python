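"""Exception hierarchy for eiodetect.

All package errors derive from :class:`EiodetectError` so callers (and the
CLI) can distinguish data problems from configuration problems.
"""


class EiodetectError(Exception):
    """Base class for all eiodetect errors."""


class ParseError(EiodetectError):
    """A record file could not be parsed (names the offending line)."""


class ValidationError(EiodetectError):
    """Parsed data violates an invariant (e.g. non-monotone timestamps)."""


class SchemaError(EiodetectError):
    """Unknown or inconsistent column schema."""


class ConfigError(EiodetectError):
    """Invalid configuration value or combination."""


class NoValidSamplesError(EiodetectError):
    """Calibration removed every point of a record."""


class TrainingError(EiodetectError):
    """A base classifier failed to train, or no weak learner beats chance."""
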