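"""Exception hierarchy.

``InputError`` (and its subclass ``ConfigError``) map to CLI exit code 1,
every other :class:`BooScoreError` to exit code 2.
"""


class BooScoreError(Exception):
    """Base class for all package errors."""


class InputError(BooScoreError):
    """Invalid user-supplied data: bad files, out-of-domain values, missing columns."""


class ConfigError(InputError):
    """Invalid configuration object (generator, card, or pipeline)."""


class UndefinedMetricError(BooScoreError):
    """A diagnostic metric's denominator is empty (single-class labels)."""


class DerivationError(BooScoreError):
    """A cutoff satisfying the requested specificity target does not exist."""


class PipelineError(BooScoreError):
    """A pipeline stage failed; the message names the stage."""
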