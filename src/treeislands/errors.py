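"""Exception hierarchy for treeislands."""


class TreeIslandsError(Exception):
    """Base class for all package errors."""


class NewickParseError(TreeIslandsError):
    """Raised when a Newick/NEXUS string cannot be parsed."""


class ValidationError(TreeIslandsError):
    """Raised when an input violates a structural contract
    (unknown label, mismatched taxon sets, incompatible supports...)."""


class ArgumentError(TreeIslandsError, ValueError):
    """Raised for out-of-range or degenerate arguments (burnin >= 1, n < 4...)."""


class GenerationError(TreeIslandsError):
    """Raised when the synthetic generator cannot realize an island spec
    within its retry budget."""
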