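"""Exception hierarchy shared across the package."""


class CasepyError(Exception):
    """Base class for all errors raised by casepy."""


class FormulaParseError(CasepyError):
    """A molecular formula string could not be parsed."""


class ValidationError(CasepyError):
    """A molecular graph or spectrum violates a structural invariant."""


class ParameterError(CasepyError):
    """An operation was called with an out-of-range parameter."""


class IngestionError(CasepyError):
    """A record could not be ingested into the knowledge base."""


class PeakListError(CasepyError):
    """A peak-list document is malformed or inconsistent."""


class ProblemBuildError(CasepyError):
    """Correlation data and molecular formula are mutually inconsistent."""
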