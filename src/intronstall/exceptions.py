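"""Exception hierarchy for the intronstall pipeline."""


class IntronstallError(Exception):
    """Base class for all pipeline errors."""


class AnnotationError(IntronstallError):
    """Unparseable annotation file or invalid gene structure."""


class EmptyPartitionError(IntronstallError):
    """A feature partition ended up with zero assigned bases."""


class EmptyTrackError(IntronstallError):
    """A coverage source yielded no signal (empty file, all reads filtered)."""


class FormatError(IntronstallError):
    """Malformed input file (bedGraph, BP table, ...)."""


class NormalizationError(IntronstallError):
    """Depth normalization impossible (zero mapped reads)."""


class ShapeMismatchError(IntronstallError):
    """Two tracks/profiles do not cover the same coordinate space."""


class EmptyProfileError(IntronstallError):
    """No gene was eligible to contribute to a metaprofile."""


class InsufficientDataError(IntronstallError):
    """Too few genes (or permutations) for the requested statistical test."""


class UndefinedStatisticError(IntronstallError):
    """A ratio statistic is undefined (zero denominator)."""


class CapacityError(IntronstallError):
    """Simulated genes cannot be placed under the simulation config."""
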