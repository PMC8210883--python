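"""Exception types shared across the package."""


class SpikeStateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpikeStateError, ValueError):
    """Invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DataError(SpikeStateError, ValueError):
    """Input data violates a precondition of an operation."""


class ModuleCollapseError(SpikeStateError, RuntimeError):
    """Iterative module refinement shrank the gene set below two genes."""

    def __init__(self, trace):
        self.trace = trace
        super().__init__(
            "module collapsed below 2 genes during refinement; "
            f"per-iteration gene counts: {[len(g) for g in trace]}"
        )
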