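"""Domain-specific exceptions.

Plain ``ValueError`` is used for generic invalid arguments; the classes here
mark failure modes callers may want to handle individually.
"""


class UnsupportedLatitudeError(ValueError):
    """Coriolis parameter too small: latitude within 1 degree of the equator."""


class IncompleteSeasonError(ValueError):
    """A season-year was requested for which not all days are present."""


class DegenerateCovarianceError(ValueError):
    """Presence covariance matrix is singular; Mahalanobis distance undefined."""


class InsufficientBackgroundError(ValueError):
    """Fewer eligible background cells than pseudo-absences requested."""


class UndefinedContributionError(ValueError):
    """A predictor never appears as an addition to any alternative model."""


class UndefinedRateError(ValueError):
    """Sensitivity or specificity undefined (a class has zero records)."""


class DisconnectedGridError(ValueError):
    """Coastline adjacency graph is not connected."""
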