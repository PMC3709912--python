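"""Exception types shared across the pipeline."""


class RehoMvpaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RehoMvpaError):
    """A configuration value violates its documented invariant."""


class FormatError(RehoMvpaError):
    """An input file or table does not match the expected format."""


class DegenerateInputError(RehoMvpaError):
    """Input is structurally valid but the statistic is undefined on it."""
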