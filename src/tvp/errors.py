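"""Exception hierarchy shared by all pipeline stages."""


class TvpError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TvpError):
    """A file violated the expected dialect (PDB, TSV, alignment ...)."""


class SelectionError(TvpError, LookupError):
    """A (chain, residue) pair could not be resolved against a structure."""


class ParameterError(TvpError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateFitError(TvpError):
    """A geometric fit is underdetermined (too few points, zero variance)."""


class DataError(TvpError):
    """Tabular inputs are inconsistent (missing rows, duplicate keys ...)."""


class PipelineError(TvpError):
    """Configuration or orchestration failure; message names the field/path."""
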