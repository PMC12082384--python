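"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class TcrCompartError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TcrCompartError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(TcrCompartError):
    """A malformed input file; the message names the column or line."""


class PipelineError(TcrCompartError):
    """A pipeline stage failed; the message names the stage and cause."""
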