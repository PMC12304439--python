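"""Exception hierarchy shared across the pipeline stages."""


class PelagifdError(Exception):
    """Base class for all package-specific errors."""


class InvalidGearError(PelagifdError):
    """Trawl geometry (opening or distance) is non-positive."""


class InvalidCatchError(PelagifdError):
    """Catch mass is negative."""


class DepthRangeError(PelagifdError):
    """A depth falls outside the sampled 20-2000 m interval."""


class ConfigError(PelagifdError):
    """A configuration value is outside its documented range."""


class CannotImputeError(PelagifdError):
    """A trait column has no observed values to impute from."""


class DegenerateSpaceError(PelagifdError):
    """All traits constant: no dissimilarity structure to embed."""


class DimensionalityError(PelagifdError):
    """Too few affinely independent species for a convex hull."""


class UndefinedIndexError(PelagifdError):
    """An index is undefined for this assemblage (e.g. FEve needs S >= 3)."""


class DegenerateNullError(PelagifdError):
    """Null distribution has zero spread; SES undefined."""
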