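"""Exception hierarchy for the ligandnet pipeline."""


class LigandNetError(Exception):
    """Base class for all ligandnet errors."""


class ParseError(LigandNetError):
    """A SMILES string could not be parsed into a connection table."""

    def __init__(self, smiles: str, ligand_id: str | None = None):
        self.smiles = smiles
        self.ligand_id = ligand_id
        super().__init__(f"unparseable SMILES for ligand {ligand_id!r}: {smiles!r}")


class LengthMismatch(LigandNetError):
    """Two binary vectors of unequal length were compared."""


class MatrixMalformed(LigandNetError):
    """A similarity/distance matrix violates symmetry, range or diagonal rules."""


class EmptyResult(LigandNetError):
    """Filtering removed every record."""


class UnclusteredLigand(LigandNetError):
    """An interaction references a ligand that belongs to no cluster."""


class EmptyTrainingSet(LigandNetError):
    """A fusion score was requested against an empty training set."""


class DegenerateLabels(LigandNetError):
    """AUC requires at least one active and one decoy."""


class InsufficientActives(LigandNetError):
    """Too few actives to split into non-empty training and test sets."""


class BackendUnavailable(LigandNetError):
    """An optional external community-detection backend is not installed."""


class EmptyOverlap(LigandNetError):
    """Two partitions share no nodes."""


class UnknownIdentifier(LigandNetError):
    """A conditional search referenced ids absent from the knowledge base."""

    def __init__(self, ids):
        self.ids = sorted(ids)
        super().__init__(f"unknown identifiers: {', '.join(self.ids)}")


class GenerationFailed(LigandNetError):
    """The synthetic generator could not reach its similarity margins."""
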