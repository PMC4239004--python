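"""Exception types shared across the package."""


class FunnelpotError(Exception):
    """Base class for all package errors."""


class PDBParseError(FunnelpotError):
    """The input file could not be parsed as PDB."""


class EmptyModelError(FunnelpotError):
    """A model ended up with zero residues."""


class HarmonizationError(FunnelpotError):
    """Native and decoy sequences cannot be reconciled by end-trimming."""


class DegenerateInputError(FunnelpotError):
    """Input is structurally valid but degenerate for the operation."""


class SolverError(FunnelpotError):
    """The QP solver failed to converge."""

    def __init__(self, message: str, solver_status: str = ""):
        super().__init__(message)
        self.solver_status = solver_status


class GenerationError(FunnelpotError):
    """Synthetic-chain generation exhausted its retry budget."""
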