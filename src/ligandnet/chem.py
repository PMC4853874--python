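"""Molecule parsing, hashed path fingerprints and binary similarity kernels.

Molecules are held as canonical SMILES with molecular weight in daltons.
Fingerprints are fixed-length binary vectors produced by the RDKit hashed
linear-path fingerprinter (all labelled paths up to ``depth`` bonds hashed
into ``n_bits`` positions), the ligand descriptor used throughout the
pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from . import defaults
from .errors import LengthMismatch, ParseError

RDLogger.DisableLog("rdApp.*")  # RDKit's own stderr chatter; we raise instead

log = logging.getLogger(__name__)

__all__ = [
    "Molecule",
    "Fingerprint",
    "parse_molecule",
    "fingerprint",
    "tanimoto",
    "binary_jaccard",
    "read_smi",
    "write_smi",
    "merge_duplicates",
    "write_fingerprints",
    "read_fingerprints",
]


@dataclass(frozen=True)
class Molecule:
    """A parsed ligand: opaque id, canonical SMILES and weight in Da."""

    ligand_id: str
    smiles: str
    mol_weight: float

    def __post_init__(self):
        if self.mol_weight <= 0:
            raise ValueError(f"non-positive molecular weight for {self.ligand_id}")

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # cannot happen for molecules built via parse_molecule
            raise ParseError(self.smiles, self.ligand_id)
        return mol


@dataclass
class Fingerprint:
    """Fixed-length binary molecular descriptor."""

    bits: np.ndarray
    n_set: int = field(default=-1)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValueError("fingerprint bits must be a flat vector")
        if self.n_set < 0:
            self.n_set = int(np.count_nonzero(self.bits))

    def __len__(self) -> int:
        return self.bits.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return len(self) == len(other) and bool(np.array_equal(self.bits, other.bits))

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, text: str, n_bits: int = defaults.FP_N_BITS) -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(text), dtype=np.uint8)
        bits = np.unpackbits(raw)[:n_bits].astype(bool)
        if bits.shape[0] != n_bits:
            raise ValueError(f"hex string encodes {bits.shape[0]} bits, expected {n_bits}")
        return cls(bits=bits)


def parse_molecule(smiles: str, ligand_id: str, mol_weight: float | None = None) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    The SMILES is canonicalized, so two input strings denoting the same
    structure yield identical molecules.  ``mol_weight`` is computed from the
    structure when not supplied.

    Raises
    ------
    ParseError
        If the SMILES has no valid connection table.
    """
    if not smiles or not smiles.strip():
        raise ParseError(smiles, ligand_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(smiles, ligand_id)
    canonical = Chem.MolToSmiles(mol)
    if mol_weight is None:
        mol_weight = float(Descriptors.MolWt(mol))
    return Molecule(ligand_id=ligand_id, smiles=canonical, mol_weight=mol_weight)


def fingerprint(
    mol: Molecule | Chem.Mol,
    n_bits: int = defaults.FP_N_BITS,
    depth: int = defaults.FP_DEPTH,
) -> Fingerprint:
    """Hashed linear-path fingerprint of ``mol``.

    Deterministic for a given structure: identical canonical SMILES give
    identical bit vectors.
    """
    rd = mol.to_rdkit() if isinstance(mol, Molecule) else mol
    bv = Chem.RDKFingerprint(rd, maxPath=depth, fpSize=n_bits)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return Fingerprint(bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors are defined as identical (similarity 1); a zero
    vector against a non-zero one scores 0.

    Raises
    ------
    LengthMismatch
        If the vectors have different lengths.
    """
    if len(a) != len(b):
        raise LengthMismatch(f"fingerprint lengths differ: {len(a)} vs {len(b)}")
    return binary_jaccard(a.bits, b.bits)


def binary_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two boolean vectors; both-empty is defined as 1.0."""
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


def merge_duplicates(molecules: list[Molecule]) -> list[Molecule]:
    """Collapse repeated ligand ids.

    Duplicates with identical canonical SMILES merge silently; conflicting
    structures keep the first occurrence and emit a warning.
    """
    seen: dict[str, Molecule] = {}
    for mol in molecules:
        prev = seen.get(mol.ligand_id)
        if prev is None:
            seen[mol.ligand_id] = mol
        elif prev.smiles != mol.smiles:
            warnings.warn(
                f"ligand {mol.ligand_id}: conflicting structures "
                f"{prev.smiles!r} vs {mol.smiles!r}; keeping the first",
                stacklevel=2,
            )
    return list(seen.values())


def read_smi(path: str | Path, strict: bool = False) -> list[Molecule]:
    """Read a ``.smi`` file (``SMILES<whitespace>ID`` per line).

    Unparseable lines raise :class:`ParseError` when ``strict`` else are
    logged and skipped.  Duplicate ids are merged per :func:`merge_duplicates`.
    """
    molecules: list[Molecule] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ligand_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            try:
                molecules.append(parse_molecule(smiles, ligand_id))
            except ParseError:
                if strict:
                    raise
                n_bad += 1
                log.warning("%s:%d: skipping unparseable SMILES %r", path, lineno, smiles)
    if n_bad:
        log.info("%s: skipped %d unparseable records", path, n_bad)
    return merge_duplicates(molecules)


def write_smi(molecules: list[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.smiles}\t{mol.ligand_id}\n")


def write_fingerprints(fps: dict[str, Fingerprint], path: str | Path) -> None:
    """Cache fingerprints as hex strings in a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("ligand_id\tfingerprint_hex\n")
        for ligand_id in sorted(fps):
            fh.write(f"{ligand_id}\t{fps[ligand_id].to_hex()}\n")


def read_fingerprints(path: str | Path, n_bits: int = defaults.FP_N_BITS) -> dict[str, Fingerprint]:
    fps: dict[str, Fingerprint] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("ligand_id"):
            raise ValueError(f"{path}: expected a 'ligand_id\\tfingerprint_hex' header")
        for line in fh:
            ligand_id, hextext = line.rstrip("\n").split("\t")
            fps[ligand_id] = Fingerprint.from_hex(hextext, n_bits=n_bits)
    return fps
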