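"""Exception hierarchy shared across the pipeline stages."""


class MeibomorphError(Exception):
    """Base class for all package errors."""


class InputError(MeibomorphError):
    """Unreadable or malformed input (file, table, config)."""


class DimensionError(MeibomorphError):
    """Empty rasters, non-positive target sizes, or mismatched mask shapes."""


class DegenerateGeometryError(MeibomorphError):
    """Geometry too degenerate to measure (zero covariance, too few chords)."""


class DegenerateTarsusError(MeibomorphError):
    """Tarsus mask empty or of zero area; density/loss undefined."""


class GenerationError(MeibomorphError):
    """Synthetic placement infeasible for the given spec/seed."""


class StratificationError(MeibomorphError):
    """A grade is missing from a training fold or split."""
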