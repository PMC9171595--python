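"""Exception hierarchy for the wardsense pipeline."""


class WardsenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(WardsenseError):
    """An invalid configuration value; the message names the offending field."""


class IntegrityError(WardsenseError):
    """Input data violate a structural precondition (overlaps, length mismatch, unknown ids)."""


class UndefinedWindowError(WardsenseError):
    """A window statistic was requested on too few samples to be defined."""


class TrainingError(WardsenseError):
    """The reference classifier cannot be trained from the provided windows."""


class LabelingError(WardsenseError):
    """An activity label was requested for a window that cannot carry one."""


class ModelSpecificationError(WardsenseError):
    """An unknown model id / outcome, or a design matrix that cannot be built."""


class StandardizationError(WardsenseError):
    """A variable cannot be z-scored (zero variance); the message names it."""


class UndefinedGroupError(WardsenseError):
    """A per-group statistic was requested for an empty group."""
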