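"""Exception types shared across the pipeline stages."""


class CernanetError(Exception):
    """Base class for all package errors."""


class ParameterError(CernanetError, ValueError):
    """A simulation or configuration parameter violates its constraints."""


class LoadError(CernanetError, ValueError):
    """An input file is missing, malformed, or internally inconsistent."""


class ContractError(CernanetError, ValueError):
    """An operation was called with inputs violating its preconditions."""


class EmptyNetworkError(CernanetError, RuntimeError):
    """Network assembly produced no nodes; downstream topology is undefined."""
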