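"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes: usage errors → 2,
incompatible phylogeny → 3, capped run → 4, domain error → 5.
"""


class CoalescentError(Exception):
    """Base class for all package errors."""


class FormatError(CoalescentError):
    """Malformed incidence-matrix input (non-binary cell, bad header, ...)."""


class PhylogenyError(CoalescentError):
    """Binary data does not admit a perfect phylogeny.

    Carries the witness pair of site labels that violates the
    compatibility criterion.
    """

    def __init__(self, message: str, witness: tuple[str, str] | None = None):
        super().__init__(message)
        self.witness = witness


class InvariantError(CoalescentError):
    """A gene-tree or event invariant was violated."""


class DomainError(CoalescentError):
    """Parameter outside its mathematical domain (e.g. theta <= 0)."""


class CapExceededError(CoalescentError):
    """A configurable node/path cap was hit before the computation finished."""

    def __init__(self, message: str, cap: int):
        super().__init__(message)
        self.cap = cap
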