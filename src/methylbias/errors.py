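"""Exception hierarchy shared by all modules."""


class MethylbiasError(Exception):
    """Base class for package errors."""


class ParameterError(MethylbiasError, ValueError):
    """An argument violates a documented precondition."""


class AlphabetError(MethylbiasError, ValueError):
    """A sequence contains characters outside {A, C, G, T} (N where allowed)."""


class ConsistencyError(MethylbiasError):
    """Internal cross-references disagree (e.g. a cytosine with no truth record)."""


class FormatError(MethylbiasError, ValueError):
    """A file does not conform to the documented dialect.

    Carries enough context (file, line, field) to locate the offending record.
    """

    def __init__(self, message: str, path=None, line: int | None = None,
                 field: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if field is not None:
            loc.append(f"field {field!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path = path
        self.line = line
        self.field = field
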