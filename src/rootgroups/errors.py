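"""Exception hierarchy shared by all pipeline stages."""


class RootgroupsError(Exception):
    """Base class for all package errors."""


class SchemaError(RootgroupsError):
    """Input file does not match the documented CSV schema."""


class ValidationError(RootgroupsError, ValueError):
    """A record violates a physical or design invariant (e.g. dry > fresh weight)."""


class DesignError(RootgroupsError):
    """Observations are inconsistent with the augmented block design layout."""


class DomainError(RootgroupsError):
    """A computation is undefined for the given input (zero denominator, n too small)."""


class ClassificationError(RootgroupsError):
    """A genotype cannot be classified (missing trait value or condition)."""


class ConfigError(RootgroupsError):
    """Pipeline configuration is invalid or infeasible."""
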