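"""Exception types shared across the package."""


class NKBreedError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NKBreedError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidGenotypeError(NKBreedError, ValueError):
    """A genotype is the wrong length or contains non-binary alleles."""


class EmptyPoolError(NKBreedError, RuntimeError):
    """A selection pool is empty; callers decide the fallback."""


class EmptyRuleSetError(NKBreedError, LookupError):
    """Rule selection was attempted on an empty rule set."""


class ConfigError(NKBreedError, ValueError):
    """A run configuration failed validation; the message names the field."""
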