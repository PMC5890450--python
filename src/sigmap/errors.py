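"""Exception hierarchy shared by all sigmap modules."""


class SigmapError(Exception):
    """Base class for all sigmap errors."""


class IntegrityError(SigmapError):
    """A map references an id that does not exist, or violates a structural invariant."""


class EntityNotFoundError(SigmapError, KeyError):
    """Lookup of an unknown entity, reaction, compartment or module id."""


class MapParseError(SigmapError):
    """Malformed input document; carries a line number when available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class MergeConflictError(SigmapError):
    """Two maps assign incompatible entity classes to the same identity key."""
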