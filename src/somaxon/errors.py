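"""Exception hierarchy for the somaxon pipeline.

Every failure mode the library raises deliberately derives from
:class:`SomaxonError`, so callers (and the CLI) can distinguish usage
problems from genuine bugs.
"""


class SomaxonError(Exception):
    """Base class for all somaxon errors."""


class DimensionError(SomaxonError, ValueError):
    """Image or tile dimensions are invalid (non-positive, wrong shape)."""


class TilingError(SomaxonError, ValueError):
    """A tiling scheme does not divide the image evenly."""


class ConfigurationError(SomaxonError, ValueError):
    """A study design, profile table or run configuration is inconsistent."""


class UsageError(SomaxonError, ValueError):
    """An operation was called with mismatched or empty inputs."""


class InsufficientDataError(SomaxonError, ValueError):
    """Too few samples to compute the requested statistic."""


class PairingError(SomaxonError, ValueError):
    """Soma and axon results cannot be paired for 2D integration."""


class TrainingError(SomaxonError, ValueError):
    """The classifier cannot be trained on the given data."""
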