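"""Exception hierarchy for hzkit.

Every error raised deliberately by the package derives from :class:`HzkitError`
so callers can catch the whole family with one clause.
"""


class HzkitError(Exception):
    """Base class for all hzkit errors."""


class ParameterError(HzkitError, ValueError):
    """A scenario, policy or model parameter violates its invariants."""


class ParseError(HzkitError, ValueError):
    """An input file could not be parsed."""


class FormatError(HzkitError, ValueError):
    """A file parsed but its content violates the expected contract
    (e.g. non-diploid genotypes)."""


class DataError(HzkitError, ValueError):
    """A dataset is unusable for the requested operation (empty, too small)."""


class GeometryError(HzkitError, ValueError):
    """Degenerate geometric input (e.g. a baseline with no extent)."""


class EstimationError(HzkitError, RuntimeError):
    """A statistical estimate is non-identifiable on the given data."""


class FitError(HzkitError, RuntimeError):
    """Model fitting could not be started or completed."""


class SelectionError(HzkitError, RuntimeError):
    """Model selection received no valid candidate fits."""


class ConfigError(HzkitError, ValueError):
    """A pipeline run configuration is invalid."""


class StageError(HzkitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
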