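"""Exception hierarchy shared across the package."""


class CnvnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CnvnetError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(CnvnetError, ValueError):
    """Input data violates a documented precondition."""


class ModelError(CnvnetError, ValueError):
    """A model object is internally inconsistent (e.g. non-monotone cluster thetas)."""


class PipelineError(CnvnetError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
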