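"""Exception hierarchy for sugarcg."""


class SugarCGError(Exception):
    """Base class for all sugarcg errors."""


class UnsupportedResidueError(SugarCGError, KeyError):
    """Raised when a residue code has no shipped template."""


class RingNotFoundError(SugarCGError, ValueError):
    """Raised for open-chain input; only closed-ring monosaccharides are modeled."""


class UnsupportedLinkageError(SugarCGError, ValueError):
    """Raised for glycosidic linkage classes outside the supported set."""


class GlycanParseError(SugarCGError, ValueError):
    """Descriptor grammar violation; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class GlycanValidationError(SugarCGError, ValueError):
    """A parsed glycan graph violates a structural invariant."""


class MappingError(SugarCGError, ValueError):
    """Atomistic-to-CG mapping failure (naming, indexing, frame shape)."""


class MissingParameterError(SugarCGError, KeyError):
    """A bonded term required by the topology has no fitted parameter."""


class FittingError(SugarCGError, ValueError):
    """Distribution extraction or parameter fitting failure."""


class PackingError(SugarCGError, RuntimeError):
    """System construction could not place all molecules."""
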