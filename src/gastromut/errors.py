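"""Exception hierarchy shared across the pipeline."""


class GastromutError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GastromutError, ValueError):
    """Malformed input file (FASTA, mutation table, config)."""


class ValidationError(GastromutError, ValueError):
    """Inputs violate an operation's contract (allele mismatch, layout mismatch...)."""


class ConfigurationError(GastromutError, ValueError):
    """A configuration value is out of its admissible range."""


class DegenerateInputError(GastromutError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-N sequence)."""


class UndefinedMetricError(GastromutError, ValueError):
    """A metric is mathematically undefined for the given inputs (e.g. single-class AUC)."""
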