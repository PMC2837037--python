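"""Exception hierarchy for the comparative BAC-mapping pipeline."""


class BacmapError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(BacmapError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class InputError(BacmapError):
    """Malformed or inconsistent input data."""


class MissingInputError(BacmapError):
    """A required input file for a pipeline stage does not exist."""

    def __init__(self, path):
        self.path = path
        super().__init__(f"required input file not found: {path}")


class LiftError(BacmapError):
    """A read could not be lifted through its anchoring contig."""


class EmptyDistributionError(BacmapError):
    """No data available to build an insert-size distribution."""
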