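"""Exception hierarchy for the senemeth pipeline."""


class SenemethError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SenemethError):
    """A file or table violates the expected on-disk format."""


class ValidationError(SenemethError):
    """An in-memory value violates a domain invariant (e.g. beta outside [0, 1])."""


class ConfigError(SenemethError):
    """A configuration or simulation parameter is inconsistent."""
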