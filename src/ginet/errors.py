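"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
GuardrailError -> 4; anything else is an ordinary traceback.
"""


class GinetError(Exception):
    """Base class for all package errors."""


class ConfigError(GinetError):
    """Invalid configuration or parameter value."""


class DataError(GinetError):
    """Malformed, empty, or inconsistent input data."""


class GuardrailError(GinetError):
    """A runtime guardrail (retry cap, bootstrap budget) was exceeded."""
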