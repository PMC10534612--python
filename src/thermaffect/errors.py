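"""Exception hierarchy for the thermaffect pipeline."""


class ThermaffectError(Exception):
    """Base class for all pipeline errors."""


class EyesNotFoundError(ThermaffectError):
    """Fewer than two eye-candidate components found in the upper face."""


class EmptyForegroundError(ThermaffectError):
    """Binarization produced no foreground, so no face box exists."""


class DegenerateDimensionError(ThermaffectError):
    """A statistic needs >= 2 rows or columns and the patch has fewer."""


class NoPairsError(ThermaffectError):
    """A co-occurrence offset has no valid pixel pairs in the patch."""


class UndefinedCorrelationError(ThermaffectError):
    """GLCM correlation is undefined because a marginal deviation is zero."""


class ZeroVarianceError(ThermaffectError):
    """A feature column has zero variance and cannot be z-scored."""
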