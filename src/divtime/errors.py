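"""Exception taxonomy shared by all divtime modules."""


class DivtimeError(Exception):
    """Base class for all divtime errors."""


class InvalidParameterError(DivtimeError, ValueError):
    """A numeric or structural parameter violates an operation's preconditions."""


class CapacityError(DivtimeError, ValueError):
    """The requested computation exceeds the documented exact-size limits."""


class FormatError(DivtimeError, ValueError):
    """Malformed graph6 / edge-list input, or a graph not representable in the format."""


class UnsupportedInputError(DivtimeError, ValueError):
    """Structurally valid input outside an operation's supported class (e.g. directed)."""


class StructuralError(DivtimeError, RuntimeError):
    """An impossible structural situation, e.g. a vertex with no in-neighbours
    on a graph that was supposed to be strongly connected."""
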