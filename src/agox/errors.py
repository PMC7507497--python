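"""Exception hierarchy for the agox pipeline."""


class AgoxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AgoxError):
    """Invalid simulation or analysis configuration."""


class AnnotationError(AgoxError):
    """Transcript annotation inconsistent with the genome or with itself."""


class InputError(AgoxError):
    """Malformed or mutually inconsistent input tables."""


class NormalizationError(AgoxError):
    """Size-factor normalization is undefined for the given counts."""
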