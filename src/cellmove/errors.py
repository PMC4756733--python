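"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A model or numerics parameter violates its constraints."""


class ConfigError(ValueError):
    """A configuration file is malformed or inconsistent."""


class PackingError(RuntimeError):
    """A hard-core point pattern cannot be packed into the requested domain."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to reach its tolerance."""
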