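"""Exception hierarchy.

Every error raised by this package derives from :class:`MalecotMapError`
so callers can catch the package's failures with a single except clause.
"""


class MalecotMapError(Exception):
    """Base class for all malecotmap errors."""


class InvalidConfigurationError(MalecotMapError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class GenerationFailureError(MalecotMapError, RuntimeError):
    """A synthetic-data generator could not satisfy its contract."""


class UndefinedLDError(MalecotMapError, ValueError):
    """LD is undefined, e.g. one of the two loci is monomorphic."""


class EmptyTableError(MalecotMapError, ValueError):
    """No eligible marker pairs under the current distance cap."""


class MapFitError(MalecotMapError, RuntimeError):
    """The LDU-map optimiser failed after all restarts."""


class LocationUnidentifiableError(MalecotMapError, RuntimeError):
    """The location RSS profile is flat; no LDU distance in the window."""


class DegenerateInputError(MalecotMapError, ValueError):
    """Input has no usable variation (e.g. constant trait)."""


class StratificationError(MalecotMapError, ValueError):
    """A genotype stratum required by an interaction model is empty."""


class CollinearityError(MalecotMapError, ValueError):
    """Conditional regressors are (near-)collinear with the focal probe."""


class IncomparableFitsError(MalecotMapError, ValueError):
    """Location fits do not share a comparable coordinate system."""


class OutOfRangeError(MalecotMapError, ValueError):
    """A query coordinate lies outside the fitted map's support."""


class ParseError(MalecotMapError, ValueError):
    """A genotype/phenotype file could not be parsed."""


class DependencyError(MalecotMapError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
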