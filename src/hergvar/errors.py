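"""Exception hierarchy for the hERG variability pipeline."""


class HergVarError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(HergVarError, ValueError):
    """A study design or simulator configuration violates its invariants."""


class SegmentationError(HergVarError, ValueError):
    """A protocol window falls outside the recorded sweep."""


class SchemaError(HergVarError, ValueError):
    """A dataset table is missing required columns or has bad types."""


class MissingSweepError(HergVarError, FileNotFoundError):
    """A manifest references a sweep file that does not exist."""


class FormatError(HergVarError, ValueError):
    """A waveform file violates the dialect (non-uniform sampling, ragged columns)."""


class ConfigurationError(HergVarError, ValueError):
    """An operation was requested with an inconsistent configuration."""


class DegenerateCellError(HergVarError, ValueError):
    """A cell's baseline hERG amplitude is non-positive; inhibition is undefined."""


class InsufficientDataError(HergVarError, ValueError):
    """Too few observations for the requested statistic."""


class FitInputError(HergVarError, ValueError):
    """Fit input fails preconditions (too few concentrations, empty subset...)."""
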