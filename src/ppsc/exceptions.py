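"""Exception types shared across the package."""


class PpscError(Exception):
    """Base class for package errors."""


class SchemaError(PpscError, ValueError):
    """Input does not match the expected shape or column layout."""


class MissingDataError(PpscError, ValueError):
    """A required threshold or cell is missing; the caller decides imputation."""


class NoQualifyingRunError(PpscError):
    """No contiguous impaired frequency run satisfies the detection rule."""


class ParameterError(PpscError, ValueError):
    """Infeasible or out-of-range configuration value."""
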