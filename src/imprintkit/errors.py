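"""Exception types shared across the pipeline."""


class ImprintkitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ImprintkitError, ValueError):
    """An input value violates a documented precondition."""


class InvalidQueryError(InvalidInputError):
    """A SNP substring query is malformed."""


class InvalidConfigError(InvalidInputError):
    """A simulation configuration is out of range."""


class UninformativeSNPError(ImprintkitError):
    """The untreated genotype is homozygous, so the SNP cannot phase alleles."""


class InconsistencyError(ImprintkitError):
    """Observed genotypes contradict Mendelian transmission."""


class InsufficientDataError(ImprintkitError):
    """Too few shared markers to reach a classification."""
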