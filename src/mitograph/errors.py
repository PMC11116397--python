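"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: ParameterError/ConfigurationError -> 2
(bad configuration), DataError/EstimationError -> 1 (bad or degenerate
data), anything else -> 1.
"""


class MitographError(Exception):
    """Base class for all package errors."""


class ParameterError(MitographError, ValueError):
    """A parameter value violates its documented invariant."""


class ConfigurationError(MitographError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class DataError(MitographError, RuntimeError):
    """Input data cannot be read or is structurally invalid."""


class EstimationError(MitographError, RuntimeError):
    """An estimator cannot produce a result from the given data."""
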