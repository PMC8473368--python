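"""Exception hierarchy for the gaitpath pipeline."""


class GaitPathError(Exception):
    """Base class for all gaitpath errors."""


class InputError(GaitPathError):
    """Missing or unreadable input (directory, manifest, checkpoint)."""


class FormatError(GaitPathError):
    """Structurally invalid data (dimension mismatch, bad manifest row)."""


class ValidationError(GaitPathError):
    """A value violates a documented contract (unknown class, wrong arity)."""


class NormalizationError(GaitPathError):
    """A frame cannot be normalized (e.g. no foreground)."""


class RenderError(GaitPathError):
    """A pose does not fit on the requested canvas."""


class CycleDetectionError(GaitPathError):
    """Too few feet-distance peaks to segment a gait cycle."""


class TrainingError(GaitPathError):
    """Training preconditions violated (single class, empty data)."""


class ConfigError(GaitPathError):
    """Invalid model or run configuration."""
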