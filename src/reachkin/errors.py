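"""Exception hierarchy.

Every package error derives from :class:`ReachkinError`; most also subclass
``ValueError`` so they behave sensibly in generic calling code.
"""


class ReachkinError(Exception):
    """Base class for all reachkin errors."""


class NonUniformSamplingError(ReachkinError, ValueError):
    """Time vector is not strictly increasing and uniform."""


class MissingChannelError(ReachkinError, ValueError):
    """Neither position nor acceleration is available in a recording."""


class TooShortError(ReachkinError, ValueError):
    """Recording has too few samples to differentiate reliably."""


class NoMovementError(ReachkinError, ValueError):
    """Onset detection found no usable movement in the search window."""


class SequencingError(ReachkinError, ValueError):
    """Event times violate the trigger <= onset <= end ordering."""


class DegenerateVarianceError(ReachkinError, ValueError):
    """Zero within-group variance with nonzero between-group variance."""


class UndefinedCorrelationError(ReachkinError, ValueError):
    """Pearson correlation undefined (zero variance or too few samples)."""


class ConfigError(ReachkinError, ValueError):
    """Invalid or inconsistent configuration."""


class FeatureExtractionError(ReachkinError, RuntimeError):
    """Failure inside feature extraction, annotated with trial identity."""

    def __init__(self, subject_id, trial_index, cause):
        self.subject_id = subject_id
        self.trial_index = trial_index
        self.cause = cause
        super().__init__(
            f"feature extraction failed for subject={subject_id!r} "
            f"trial={trial_index}: {cause}"
        )
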