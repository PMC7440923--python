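"""Package-wide exception types."""


class CagefoldError(Exception):
    """Base class for package errors."""


class FitConvergenceError(CagefoldError):
    """A nonlinear fit failed to converge; carries the diagnostics message."""


class TableFormatError(CagefoldError):
    """A delimited-text table violated its schema (message names the line)."""


class PipelineError(CagefoldError):
    """A pipeline stage failed; message names the stage."""
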