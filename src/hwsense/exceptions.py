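"""Exception types raised by the pipeline."""


class HwsenseError(Exception):
    """Base class for package-specific errors."""


class SchemaError(HwsenseError):
    """An input table is missing a required column."""


class DuplicateRecordError(HwsenseError):
    """An input table contains duplicate (station, date) records."""


class MappingError(HwsenseError):
    """A county in an alert file is absent from the county->region map."""


class AlignmentError(HwsenseError):
    """Two daily series that must share the same dates do not."""


class ConvergenceError(HwsenseError):
    """A maximum-likelihood fit failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateDesignError(HwsenseError):
    """A design-matrix column is constant or separates the outcome."""

    def __init__(self, message, column=None):
        super().__init__(message)
        self.column = column
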