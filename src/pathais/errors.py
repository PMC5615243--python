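"""Exception hierarchy shared across the package."""


class PathAISError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PathAISError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(PathAISError):
    """A required fitness measurement is absent (see preprocess.impute_missing)."""


class CyclicNetworkError(InvalidInputError):
    """A candidate pathway network contains a directed cycle."""


class ScaffoldViolationError(InvalidInputError):
    """A directed edge has no supporting protein-interaction scaffold edge."""


class NoMoveError(PathAISError):
    """The legal move set of the sampler is empty (empty scaffold)."""


class ImputationError(MissingDataError):
    """A gene's interaction profile is too sparse to regress."""

    def __init__(self, gene: str, message: str | None = None):
        self.gene = gene
        super().__init__(message or f"cannot impute profile of gene {gene!r}")
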