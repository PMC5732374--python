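"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2,
degenerate inputs (e.g. an all-zero dissimilarity) exit 3.
"""


class RfcluError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RfcluError, ValueError):
    """Input violates a documented contract (bad genotype entry, length
    mismatch, invalid configuration)."""


class FormatError(ValidationError):
    """A file could not be parsed (ragged rows, unknown dialect)."""


class MissingGenotypeError(ValidationError):
    """A missing-value token was found in a genotype file.

    Missing genotypes are rejected rather than imputed; callers should
    filter or impute markers upstream before loading.
    """


class DegenerateInputError(RfcluError):
    """The computation cannot proceed (e.g. all pairwise dissimilarities
    are zero so no embedding exists)."""
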