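"""Exception hierarchy for cfmethylome."""


class CfmeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CfmeError):
    """A malformed record in an input file.

    Carries the file path and 1-based line number of the offending record.
    """

    def __init__(self, path, line_number, message):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class DuplicateRecordError(CfmeError):
    """Two records claim the same locus where one is expected."""


class ValidationError(CfmeError):
    """A configuration or precondition violation."""


class DegenerateStatisticError(CfmeError):
    """A statistic is undefined on the given data (e.g. MAD of zero)."""


class PipelineError(CfmeError):
    """A pipeline stage cannot run (usually a missing upstream output)."""
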