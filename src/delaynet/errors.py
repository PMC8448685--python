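"""Exception hierarchy shared across the package."""


class DelaynetError(Exception):
    """Base class for all package errors."""


class DomainError(DelaynetError, ValueError):
    """An input lies outside the mathematical domain of a formula."""


class ValidationError(DelaynetError, ValueError):
    """A container violates its structural invariants."""


class ConfigError(DelaynetError, ValueError):
    """A configuration object violates its invariants.

    The message lists *all* violations, not just the first one found.
    """


class EmptyNetworkError(DelaynetError):
    """Group averaging retained no edges under the inclusion rule."""


class RegressionError(DelaynetError, ValueError):
    """Degenerate input to a regression or summary statistic."""


class GenerationError(DelaynetError, ValueError):
    """Synthetic data cannot be generated under the requested constraints."""


class GraphError(DelaynetError, ValueError):
    """Invalid input to a graph-theoretical operation."""


class IntegrationError(DelaynetError, RuntimeError):
    """Numerical failure inside the Kuramoto integrator."""


class PipelineError(DelaynetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
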