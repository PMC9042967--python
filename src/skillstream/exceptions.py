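"""Exception hierarchy for the skillstream pipeline.

Every stage raises a subclass of :class:`SkillstreamError` so the CLI can map
failures onto its exit-code contract (2 config, 3 data, 4 training).
"""


class SkillstreamError(Exception):
    """Base class for all skillstream errors."""


class InvalidConfigError(SkillstreamError):
    """A trial/cohort configuration violates its invariants."""


class MalformedStreamError(SkillstreamError):
    """A raw stream has non-increasing or duplicate timestamps."""


class TooShortTrialError(SkillstreamError):
    """A stream is shorter than one 0.2 s metric window."""


class DegenerateFeatureError(SkillstreamError):
    """A metric is constant across the training pool; z-scoring undefined."""

    def __init__(self, metric_name: str):
        self.metric_name = metric_name
        super().__init__(
            f"metric {metric_name!r} is constant across the training pool; "
            "its standard deviation is zero and z-score normalization is undefined"
        )


class FeatureOrderError(SkillstreamError):
    """A trial's metric manifest does not match the model's manifest."""


class CannotSplitError(SkillstreamError):
    """Too few participants to form train/validation/test subsets."""


class InvalidSpecError(SkillstreamError):
    """A model specification violates its invariants."""


class InvalidArgumentError(SkillstreamError):
    """A numeric argument is out of its admissible range."""


class TrainingDivergedError(SkillstreamError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class InvalidLevelError(SkillstreamError):
    """An expertise level label is outside the closed four-level vocabulary."""


class NoTrialsError(SkillstreamError):
    """A participant aggregate was requested over an empty trial list."""


class InsufficientGroupError(SkillstreamError):
    """A comparison group has fewer than two observations."""


class DegenerateRegressionError(SkillstreamError):
    """The regression predictor is constant; the slope is undefined."""
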