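"""Exception hierarchy for the rknet package.

Every error condition named in a module contract maps to one class here so
callers can catch by type rather than by message grepping.
"""


class RknetError(Exception):
    """Base class for all rknet errors."""


# --- imgio ---------------------------------------------------------------


class NoInputError(RknetError):
    """Raised when an input directory contains no readable image ("no input")."""


class InconsistentSeriesError(RknetError):
    """Files in one directory belong to different series ("inconsistent series")."""


class InconsistentGeometryError(RknetError):
    """In-plane dimensions differ across slices ("inconsistent geometry")."""


class FormatError(RknetError):
    """Unreadable or truncated volume file ("format error")."""


class NotAVolumeError(RknetError):
    """Input has fewer than 3 dimensions ("not a volume")."""


class InvalidWindowError(RknetError):
    """Window width is not strictly positive ("invalid window")."""


class WriteError(RknetError):
    """Output path not writable ("I/O error")."""


# --- features ------------------------------------------------------------


class InvalidInputError(RknetError):
    """Non-finite pixels or feature values ("invalid input")."""


class AdapterUnavailableError(RknetError):
    """No CNN adapter registered, or the adapter violated its contract
    ("adapter unavailable")."""


class DimensionMismatchError(RknetError):
    """Ragged feature rows ("dimension mismatch")."""


class DuplicateSliceError(RknetError):
    """Duplicate (patient, series, slice) keys ("duplicate slice")."""


# --- clustering ----------------------------------------------------------


class TooFewSamplesError(RknetError):
    """n < k ("too few samples")."""


class InvalidAssignmentError(RknetError):
    """Cluster label out of range ("invalid assignment")."""


class OracleCapError(RknetError):
    """Exhaustive-search instance too large ("oracle cap exceeded")."""


class NoExemplarsError(RknetError):
    """Exemplar mapping requested without any exemplar in the data
    ("no exemplars")."""


class AmbiguousMappingError(RknetError):
    """Exemplar counts tie between clusters ("ambiguous mapping")."""


# --- metrics -------------------------------------------------------------


class LengthMismatchError(RknetError):
    """Prediction and truth label lists differ in length ("length mismatch")."""


class NotBinaryError(RknetError):
    """More than two distinct labels ("not binary")."""


# --- pipeline ------------------------------------------------------------


class EmptyRunError(RknetError):
    """No series ingested successfully ("empty run")."""


# --- synthetic -----------------------------------------------------------


class BadTumorRunError(RknetError):
    """Tumor slice interval outside the volume ("bad tumor_run")."""


class DegenerateSplitError(RknetError):
    """Train/test split with an empty side ("degenerate split")."""


# --- diagnostic_demo -----------------------------------------------------


class DegenerateLabelsError(RknetError):
    """Training labels contain a single class ("degenerate labels")."""


class ConfigError(RknetError):
    """Invalid configuration value."""
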