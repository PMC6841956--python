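"""Exception types shared across the package."""


class PggsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PggsimError):
    """Invalid configuration value or malformed config file."""


class ConvergenceError(PggsimError):
    """An iterative solver failed to converge within its iteration cap."""


class DegenerateSelectionError(PggsimError):
    """Fitness-proportional selection is undefined (no positive fitness)."""
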