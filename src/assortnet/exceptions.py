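"""Exception hierarchy for assortnet."""


class AssortnetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AssortnetError, ValueError):
    """A parameter is outside its allowed range."""


class NoEdgesError(AssortnetError, ValueError):
    """The operation requires a network with at least one edge."""


class DegenerateInputError(AssortnetError, ValueError):
    """Input is degenerate (all-zero block, constant signal, constant covariate)."""


class ConfigError(AssortnetError, ValueError):
    """A synthetic-cohort or experiment configuration is invalid."""


class InfeasibleConfigError(ConfigError):
    """A requested density/effect combination cannot be realized by rewiring."""


class CohortIOError(AssortnetError, ValueError):
    """A cohort directory is malformed or incomplete."""


class TaskError(AssortnetError, ValueError):
    """A classification task references a group absent from the cohort."""
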