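"""Exception types shared across the package."""


class ChemontogenError(Exception):
    """Base class for all package errors."""


class SmilesParseError(ChemontogenError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str, message: str, position: int | None = None):
        self.smiles = smiles
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{where}: {message}")


class StructureError(ChemontogenError):
    """Raised when a parsed structure is chemically invalid (e.g. valence)."""


class CanonicalizationError(ChemontogenError):
    """Raised when a pattern graph cannot be canonicalized."""


class FragmentLimitError(ChemontogenError):
    """Raised when fragment enumeration would exceed the configured cap."""


class UnsupportedAxiomError(ChemontogenError):
    """Raised when an OWL document contains axiom shapes outside the supported profile."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            "unsupported axiom shapes: " + "; ".join(str(o) for o in self.offenders)
        )


class MergeConflictError(ChemontogenError):
    """Raised when two ontologies define the same class URI differently."""
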