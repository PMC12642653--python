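"""Exception types shared across the package."""


class KircError(Exception):
    """Base class for package-specific failures."""


class UnknownChainError(KircError, KeyError):
    """A chain id was requested that the structure does not contain."""


class EmptyChainError(KircError, ValueError):
    """A chain with zero residues cannot take part in geometry operations."""


class ShapeMismatchError(KircError, ValueError):
    """A matrix does not match its declared dimensions."""


class CrosslinkMappingError(KircError, KeyError):
    """A crosslink residue could not be resolved to a C-alpha atom."""


class ParameterError(KircError, ValueError):
    """A parameter is outside its declared range."""


class CapacityError(KircError, ValueError):
    """More unique pairs were requested than the universe can supply."""


class ShortfallError(KircError, RuntimeError):
    """Too few candidate negatives survived contamination filtering."""
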