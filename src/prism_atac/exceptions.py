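"""Typed errors raised by the variability pipeline.

Input-shape problems raise subclasses of :class:`InputError`; failures that
arise during a computation (degenerate geometry, impossible background
matching) raise subclasses of :class:`ComputationError`.  The CLI maps the
two families to distinct exit codes.
"""


class PrismError(Exception):
    """Base class for all package-specific errors."""


class InputError(PrismError):
    """Malformed or inconsistent user inputs."""


class ComputationError(PrismError):
    """A well-formed input on which the requested quantity is undefined."""


class DimensionMismatchError(InputError):
    """Matrix shape is inconsistent with the peak and barcode sidecar files."""


class DuplicatePeakError(InputError):
    """Two peaks share identical (chrom, start, end) coordinates."""


class MissingChromosomeError(InputError):
    """A peak references a chromosome absent from the genome FASTA."""


class EmptyFeatureSetError(ComputationError):
    """A feature interval set overlaps no peak in the universe."""


class UndefinedAngleError(ComputationError):
    """Angular cosine distance requested for an all-zero vector."""


class InsufficientCellsError(ComputationError):
    """Fewer than three usable cells remain after zero-cell filtering."""


class UnmatchablePeakError(ComputationError):
    """No eligible background candidate exists for some original peak."""


class DegenerateBackgroundError(ComputationError):
    """All background variabilities are zero; the correction ratio is undefined."""


class TooFewPointsError(ComputationError):
    """A curve statistic was requested on too short a vector."""
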