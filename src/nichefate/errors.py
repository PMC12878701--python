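"""Exception hierarchy shared across the pipeline."""


class NicheFateError(Exception):
    """Base class for all pipeline errors."""


class FormatError(NicheFateError):
    """An on-disk file does not conform to its declared format."""


class ValidationError(NicheFateError):
    """A parsed object violates a structural invariant."""


class ConfigError(NicheFateError):
    """A configuration value is missing, malformed or inconsistent."""
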