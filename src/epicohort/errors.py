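"""Exception hierarchy shared across the pipeline stages."""


class EpicohortError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(EpicohortError, ValueError):
    """A run or cohort configuration is invalid (bad field, missing path)."""


class InputError(EpicohortError, ValueError):
    """Input data violate an operation's precondition."""
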