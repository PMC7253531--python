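"""Exception hierarchy for the capheno pipeline."""


class CaphenoError(Exception):
    """Base class for all capheno errors."""


class ParameterError(CaphenoError, ValueError):
    """A parameter violates its documented domain (rate < 0, even window, ...)."""


class PlacementError(CaphenoError, ValueError):
    """A soma center does not leave room for its ROI inside the frame."""


class BoundsError(CaphenoError, IndexError):
    """An ROI falls (partially) outside the movie frame."""


class DegenerateBaselineError(CaphenoError, ValueError):
    """The estimated baseline F0 is not strictly positive."""


class TrainingError(CaphenoError, ValueError):
    """The screening classifier cannot be trained (e.g. single-class labels)."""


class InputError(CaphenoError, ValueError):
    """Malformed analysis input (unsorted spike train, dimension mismatch, ...)."""


class ConfigError(CaphenoError, ValueError):
    """Invalid pipeline configuration; message carries the offending key path."""


class DependencyError(CaphenoError, FileNotFoundError):
    """A pipeline stage is missing an upstream artifact; names the file."""
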