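"""Exception hierarchy shared across the package."""


class EfwSensError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EfwSensError, ValueError):
    """An input violates a documented contract (bounds, schema, ranges)."""


class MissingParameterError(EfwSensError, KeyError):
    """A formula was evaluated without one of its required biometric parameters."""

    def __init__(self, formula: str, parameter: str):
        self.formula = formula
        self.parameter = parameter
        super().__init__(f"formula {formula!r}: missing parameter {parameter!r}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class UnknownFormulaError(EfwSensError, KeyError):
    """A formula name was not found in the registry."""

    def __init__(self, name: str):
        super().__init__(f"unknown formula {name!r}")

    def __str__(self) -> str:
        return self.args[0]


class NoDataError(EfwSensError, LookupError):
    """A chart has no usable record for the requested week/parameter.

    Pipelines catch this to skip a (dataset, week) pair rather than abort.
    """


class ChartFormatError(ValidationError):
    """A chart file is malformed; the message names the offending row."""


class DegenerateModelError(EfwSensError, ArithmeticError):
    """Model output is (numerically) constant: total variance is not positive,
    so normalized sensitivity indices are undefined."""
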