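"""Typed exceptions raised across the pipeline.

Every malformed input raises one of these; nothing is silently dropped.
"""


class TriploidASEError(Exception):
    """Base class for all package errors."""


class SchemaError(TriploidASEError):
    """A table violates its declared schema (missing column, bad value...)."""


class OrientationError(SchemaError):
    """An allele pair lists its members with swapped subgenome labels."""


class DuplicationError(SchemaError):
    """A gene or identifier appears more than once where uniqueness is required."""


class ConfigError(TriploidASEError):
    """Invalid or inconsistent configuration values."""


class NormalizationError(TriploidASEError):
    """Size factors cannot be computed (e.g. no gene positive in all samples)."""


class PairLookupError(TriploidASEError):
    """An allele pair references a gene absent from the expression matrix."""


class DomainError(TriploidASEError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class ConsistencyError(TriploidASEError):
    """Internally inconsistent inputs (e.g. more tested pairs than DEG alleles)."""
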