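"""Exception hierarchy shared across the package."""


class BloodmealError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BloodmealError):
    """A delimited-text input is malformed (missing columns, bad rows)."""


class TaxonomyError(BloodmealError, LookupError):
    """A host species has no entry in the host-group taxonomy."""


class UnclassifiedLandCoverError(BloodmealError, ValueError):
    """A land-cover class code falls outside the urban/rural/natural ranges."""


class LandUseTieError(BloodmealError, ValueError):
    """Two or more land-cover proportions tie for the maximum."""


class EmptyDatasetError(BloodmealError, ValueError):
    """An operation requiring records received none."""


class DegenerateMatrixError(BloodmealError, ValueError):
    """A presence-absence matrix has fewer than 2 rows or columns."""


class DegenerateTableError(BloodmealError, ValueError):
    """A contingency table reduces below 2x2 after dropping zero margins."""


class ConfigError(BloodmealError, ValueError):
    """A generator or analysis configuration is inconsistent."""
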