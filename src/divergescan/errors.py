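"""Exception types shared across the package."""


class DivergescanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DivergescanError):
    """A simulation or pipeline configuration is infeasible or inconsistent."""


class ParseError(DivergescanError):
    """An input file violates its format contract.

    Where possible the message names the offending line number.
    """


class MissingDataError(DivergescanError):
    """An operation received no usable data (e.g. empty cytosine report)."""
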