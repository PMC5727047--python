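"""Exception types shared across the pipeline stages."""


class ImmunosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ImmunosigError):
    """A cohort or pipeline configuration field is invalid; names the field."""


class SchemaError(ImmunosigError):
    """An input table violates the long-format schema; names row and field."""


class FeatureDisabledError(ImmunosigError):
    """An optional feature (e.g. cytokine simulation) was requested without its config."""


class EmptyTissueError(ImmunosigError):
    """No mouse has a complete variable panel for the requested tissue."""


class DegenerateVariableError(ImmunosigError):
    """A variable is constant and cannot be standardized; names the variable."""


class TooFewSamplesError(ImmunosigError):
    """Fewer samples than the 70/15/15 split (or a fold scheme) can accommodate."""


class DegenerateLabelError(ImmunosigError):
    """Only one class present where both control and immunized mice are required."""
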