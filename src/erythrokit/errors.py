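"""Exception hierarchy shared across the toolkit."""


class ErythrokitError(Exception):
    """Base class for all erythrokit errors."""


class ConfigurationError(ErythrokitError, ValueError):
    """Invalid specification, parameter set, or pipeline configuration."""


class AnalysisError(ErythrokitError, ValueError):
    """An analysis cannot be carried out on the supplied data."""
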