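"""Exception hierarchy shared across the package."""


class FuncnetError(Exception):
    """Base class for all funcnet errors."""


class GenomeFormatError(FuncnetError):
    """Malformed genome table (duplicate primary IDs, synonym collisions...)."""


class EdgeListError(FuncnetError):
    """Malformed or empty edge-list input."""


class BinaryFormatError(FuncnetError):
    """Corrupt, truncated, or incompatible binary network file."""


class ProfileError(FuncnetError):
    """Malformed expression-profile input."""


class DatabaseError(FuncnetError):
    """Inconsistent or empty network database."""


class QueryError(FuncnetError):
    """Unusable query (no genes resolved, empty query...)."""


class ConvergenceError(FuncnetError):
    """Iterative solver failed to reach tolerance within the iteration budget."""
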