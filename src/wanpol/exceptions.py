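"""Exception hierarchy for wanpol."""


class WanpolError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WanpolError, ValueError):
    """Malformed or non-finite input."""


class DegenerateCellError(ValidationError):
    """Lattice vectors are linearly dependent (zero cell volume)."""


class IllConditionedError(WanpolError):
    """Singular kernel system; increase the regularization."""


class InsufficientDataError(WanpolError):
    """Too few samples or environments for the requested operation."""


class AmbiguousBranchError(WanpolError):
    """Residual within tolerance of a half-integer; branch undecidable."""

    def __init__(self, message, indices=()):
        super().__init__(message)
        self.indices = tuple(indices)


class UnwrapFailureError(WanpolError):
    """No single-branch probe subset found within the restart budget."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class TieError(WanpolError):
    """Exact tie in a nearest-atom assignment."""


class RepairFailureError(WanpolError):
    """Wannier-center miscounts not resolvable by bonded-pair transfer."""

    def __init__(self, message, atoms=()):
        super().__init__(message)
        self.atoms = tuple(atoms)


class NeutralityError(ValidationError):
    """Valence charges and Wannier centers do not balance."""


class NoPeakError(WanpolError):
    """No local maximum found in the requested spectral window."""


class TopologyError(WanpolError):
    """Molecular connectivity could not be identified."""


class PackingError(WanpolError):
    """Could not place molecules without overlap; enlarge the box."""


class ParseError(WanpolError):
    """Malformed input file."""
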