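"""Exception types shared across the package."""


class NmloopsError(Exception):
    """Base class for package errors."""


class InvalidParameterError(NmloopsError, ValueError):
    """A parameter violates its documented constraints."""


class ParseError(NmloopsError, ValueError):
    """An input file failed validation; message carries path/line context."""


class MonotonicityError(NmloopsError, ValueError):
    """A positivity pattern is inconsistent with outside-in digestion."""


class QCError(NmloopsError, RuntimeError):
    """A quality-control gate failed (e.g. no scorable position calls)."""
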