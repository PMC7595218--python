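"""Exception hierarchy shared across the pipeline stages."""


class CnvStratError(Exception):
    """Base class for all package errors."""


class SchemaError(CnvStratError):
    """CSV header or feature schema does not match expectations."""


class IntegrityError(CnvStratError):
    """Duplicate patient ids or otherwise inconsistent records."""


class DomainError(CnvStratError):
    """An argument is outside the mathematically valid domain."""


class EmptyCohortError(CnvStratError):
    """An operation received zero patients."""


class InsufficientDataError(CnvStratError):
    """Too few rows for the requested decomposition or fit."""


class DegeneratePartitionError(CnvStratError):
    """A clustering produced an empty cluster or all-identical data."""


class ScoringError(CnvStratError):
    """A required score covariate is missing."""


class ConvergenceError(CnvStratError):
    """A model fit failed to converge (e.g. perfect separation)."""


class CollinearityError(CnvStratError):
    """Singular information or rank-deficient design matrix."""


class LabelingError(CnvStratError):
    """Cluster semantic labeling is ambiguous (tied statistics)."""
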