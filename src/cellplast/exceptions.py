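"""Exception hierarchy."""


class CellplastError(Exception):
    """Base class for all package errors."""


class FormatError(CellplastError, ValueError):
    """A file could not be parsed or its dimensions disagree with its sidecars."""


class ValidationError(CellplastError, ValueError):
    """An in-memory object violates its contract (duplicate ids, bad shapes...)."""


class EmptyResultError(CellplastError, RuntimeError):
    """An operation removed or excluded everything; downstream work is impossible."""
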