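"""Exception hierarchy shared across the package."""


class GrowthMicroError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GrowthMicroError, ValueError):
    """An argument violated a documented precondition."""


class OutOfRangeError(GrowthMicroError, ValueError):
    """A query fell outside the supported (age) range."""


class FormatError(GrowthMicroError, ValueError):
    """A file did not conform to the expected on-disk format."""


class MappingError(GrowthMicroError, KeyError):
    """A taxon could not be mapped onto the taxonomy tree."""


class ConfigurationError(GrowthMicroError, ValueError):
    """Required labels/settings are missing from the data or config."""


class SingularDesignError(GrowthMicroError, ValueError):
    """A regression design matrix is rank deficient.

    ``columns`` names the offending (collinear) columns when identifiable.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class DegenerateFitError(GrowthMicroError, ValueError):
    """A fit succeeded but produced a degenerate result (e.g. zero residual sd)."""


class UndefinedDiversityError(GrowthMicroError, ValueError):
    """Diversity is undefined for one or more samples (all-zero counts)."""


class DegenerateCovarianceError(GrowthMicroError, ValueError):
    """A coefficient covariance surface has no usable eigenvalues."""


class JoinError(GrowthMicroError, ValueError):
    """Tables could not be joined on shared ids.

    ``orphans`` lists ids present on one side only.
    """

    def __init__(self, message, orphans=()):
        super().__init__(message)
        self.orphans = tuple(orphans)
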