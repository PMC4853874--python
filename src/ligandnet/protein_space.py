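"""Interaction filtering, protein annotation and protein-protein similarity.

A protein is annotated by the ligand clusters it binds: a bit vector with
one position per cluster, set when the protein has at least one retained
interaction with any member of that cluster.  Two proteins are then
compared by the Jaccard index of their bit vectors (the ligand-cluster
similarity) or by ``1 - distance`` from a precomputed global sequence
distance matrix (the sequence similarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import defaults
from .chem import Molecule, binary_jaccard
from .clustering import LigandCluster
from .errors import EmptyResult, MatrixMalformed, UnclusteredLigand

log = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "ProteinRecord",
    "ClusterProfile",
    "SimilarityMatrix",
    "FilterReport",
    "filter_interactions",
    "annotate_proteins",
    "jaccard_similarity_matrix",
    "sequence_similarity_matrix",
    "promiscuity_stats",
    "PromiscuityStats",
    "read_interactions_tsv",
    "write_interactions_tsv",
    "read_fasta",
    "write_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_profiles_tsv",
]

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class InteractionRecord:
    """One ligand-protein binding measurement."""

    ligand_id: str
    protein_id: str
    affinity_type: str
    affinity_value_nM: float

    def __post_init__(self):
        if self.affinity_value_nM <= 0:
            raise ValueError(
                f"non-positive affinity for {self.ligand_id}/{self.protein_id}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A target protein sequence with an optional gene-family label.

    Residues outside the 20 standard amino acids are mapped to ``X`` at
    construction (counted in the log), so the stored alphabet is always
    the standard residues plus X.
    """

    protein_id: str
    sequence: str
    family: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        cleaned = "".join(c if c in _STANDARD_RESIDUES or c == "X" else "X" for c in seq)
        n_odd = sum(1 for a, b in zip(seq, cleaned) if a != b)
        if n_odd:
            log.debug("%s: %d non-standard residues mapped to X", self.protein_id, n_odd)
        object.__setattr__(self, "sequence", cleaned)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ClusterProfile:
    """Per-protein bit vector over ligand clusters."""

    protein_id: str
    bits: np.ndarray
    n_set: int = -1

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.n_set < 0:
            self.n_set = int(np.count_nonzero(self.bits))

    def on_clusters(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


@dataclass
class SimilarityMatrix:
    """Symmetric protein-protein similarity with unit diagonal."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "ligand_cluster" or "sequence"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixMalformed(f"{self.values.shape} matrix for {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise MatrixMalformed("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise MatrixMalformed("similarities outside [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise MatrixMalformed("similarity diagonal must be 1")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_interactions`."""

    n_input: int = 0
    unresolved_ligand: int = 0
    unresolved_protein: int = 0
    bad_affinity_type: int = 0
    affinity_rule: int = 0
    mol_weight_rule: int = 0
    seq_length_rule: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_interactions(
    records: list[InteractionRecord],
    ligands: dict[str, Molecule],
    proteins: dict[str, ProteinRecord],
    max_affinity_nM: float = defaults.MAX_AFFINITY_NM,
    max_mw_Da: float = defaults.MAX_LIGAND_MW_DA,
    min_seq_len: int = defaults.MIN_PROTEIN_LENGTH,
) -> tuple[list[InteractionRecord], FilterReport]:
    """Apply the three interaction filters.

    A record is kept iff its affinity is at most ``max_affinity_nM``
    (inclusive: 10 uM passes), the ligand is strictly lighter than
    ``max_mw_Da`` and the protein is strictly longer than ``min_seq_len``
    residues.  Records whose ligand/protein cannot be resolved, or whose
    affinity type is not Ki/Kd/EC50/IC50, are dropped and counted.  Each
    dropped record is charged to the first rule it fails, in the order:
    resolution, affinity type, affinity, weight, length.

    Raises
    ------
    EmptyResult
        If no record survives.
    """
    report = FilterReport(n_input=len(records))
    kept: list[InteractionRecord] = []
    for rec in records:
        if rec.ligand_id not in ligands:
            report.unresolved_ligand += 1
            continue
        if rec.protein_id not in proteins:
            report.unresolved_protein += 1
            continue
        if rec.affinity_type not in defaults.ACCEPTED_AFFINITY_TYPES:
            report.bad_affinity_type += 1
            continue
        if rec.affinity_value_nM > max_affinity_nM:
            report.affinity_rule += 1
            continue
        if ligands[rec.ligand_id].mol_weight >= max_mw_Da:
            report.mol_weight_rule += 1
            continue
        if proteins[rec.protein_id].length <= min_seq_len:
            report.seq_length_rule += 1
            continue
        kept.append(rec)
    report.n_kept = len(kept)
    if not kept:
        raise EmptyResult("no interaction survived the filters")
    return kept, report


def annotate_proteins(
    records: list[InteractionRecord],
    clusters: list[LigandCluster],
) -> dict[str, ClusterProfile]:
    """One :class:`ClusterProfile` per protein appearing in ``records``.

    Bit ``i`` (ordered by ``cluster_id``) is set when the protein binds at
    least one member of cluster ``i``; two proteins binding different
    ligands of the same cluster get the same bit.

    Raises
    ------
    UnclusteredLigand
        If a record's ligand belongs to no cluster.
    """
    order = sorted(clusters, key=lambda c: c.cluster_id)
    col = {c.cluster_id: k for k, c in enumerate(order)}
    ligand_to_cluster: dict[str, int] = {}
    for c in order:
        for m in c.member_ids:
            ligand_to_cluster[m] = c.cluster_id
    profiles: dict[str, np.ndarray] = {}
    for rec in records:
        cid = ligand_to_cluster.get(rec.ligand_id)
        if cid is None:
            raise UnclusteredLigand(f"ligand {rec.ligand_id!r} is in no cluster")
        bits = profiles.setdefault(rec.protein_id, np.zeros(len(order), dtype=bool))
        bits[col[cid]] = True
    return {
        pid: ClusterProfile(protein_id=pid, bits=bits)
        for pid, bits in sorted(profiles.items())
    }


def jaccard_similarity_matrix(profiles: dict[str, ClusterProfile]) -> SimilarityMatrix:
    """Pairwise Jaccard index of protein cluster profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = sorted(profiles)
    for pid in ids:
        assert profiles[pid].n_set >= 1, f"all-zero profile for {pid}"
    B = np.stack([profiles[p].bits for p in ids]).astype(np.int32)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    values = inter / np.maximum(union, 1)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, kind="ligand_cluster")


def sequence_similarity_matrix(distances: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    """Convert a global sequence distance matrix into similarity = 1 - d.

    Raises
    ------
    MatrixMalformed
        On asymmetry beyond 1e-9, out-of-range values or a non-zero
        diagonal.
    """
    distances = np.asarray(distances, dtype=float)
    n = len(ids)
    if distances.shape != (n, n):
        raise MatrixMalformed(f"{distances.shape} distance matrix for {n} ids")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise MatrixMalformed("distance matrix is not symmetric")
    if distances.min() < -1e-12 or distances.max() > 1 + 1e-12:
        raise MatrixMalformed("distances outside [0, 1]")
    if not np.allclose(np.diag(distances), 0.0, atol=1e-9):
        raise MatrixMalformed("distance diagonal must be 0")
    values = np.clip(1.0 - distances, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=list(ids), values=values, kind="sequence")


@dataclass
class PromiscuityStats:
    """Descriptive promiscuity tables over ligands, clusters and proteins."""

    ligand_targets: pd.DataFrame     # ligand_id, n_targets
    cluster_stats: pd.DataFrame      # cluster_id, size, n_targets, avg_mol_weight
    protein_stats: pd.DataFrame      # protein_id, n_ligands, n_clusters
    family_clusters: pd.DataFrame | None = None  # family, n_clusters


def promiscuity_stats(
    records: list[InteractionRecord],
    clusters: list[LigandCluster],
    profiles: dict[str, ClusterProfile],
    families: dict[str, str] | None = None,
) -> PromiscuityStats:
    """Target counts per ligand and cluster, ligand/cluster counts per protein.

    A cluster's target count is the size of the union of its members'
    target sets.  With ``families`` given (protein -> family label), the
    per-family table counts the distinct clusters bound by any member.
    """
    ligand_targets: dict[str, set[str]] = {}
    protein_ligands: dict[str, set[str]] = {}
    for rec in records:
        ligand_targets.setdefault(rec.ligand_id, set()).add(rec.protein_id)
        protein_ligands.setdefault(rec.protein_id, set()).add(rec.ligand_id)

    lt = pd.DataFrame(
        [(lig, len(t)) for lig, t in sorted(ligand_targets.items())],
        columns=["ligand_id", "n_targets"],
    )
    cluster_rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        targets: set[str] = set()
        for m in c.member_ids:
            targets |= ligand_targets.get(m, set())
        cluster_rows.append((c.cluster_id, c.size, len(targets), c.avg_mol_weight))
    cs = pd.DataFrame(
        cluster_rows, columns=["cluster_id", "size", "n_targets", "avg_mol_weight"]
    )
    protein_rows = [
        (pid, len(protein_ligands.get(pid, set())), profiles[pid].n_set)
        for pid in sorted(profiles)
    ]
    ps = pd.DataFrame(protein_rows, columns=["protein_id", "n_ligands", "n_clusters"])

    fam = None
    if families is not None:
        fam_clusters: dict[str, set[int]] = {}
        for pid, profile in profiles.items():
            label = families.get(pid, "unassigned")
            fam_clusters.setdefault(label, set()).update(profile.on_clusters())
        fam = pd.DataFrame(
            [(f, len(cl)) for f, cl in sorted(fam_clusters.items())],
            columns=["family", "n_clusters"],
        )
    return PromiscuityStats(lt, cs, ps, fam)


# ---------------------------------------------------------------------------
# file dialects


def read_interactions_tsv(
    path: str | Path,
) -> tuple[list[InteractionRecord], dict[str, Molecule]]:
    """Read the interaction table and parse its ligands.

    Expected columns: ``ligand_id``, ``smiles``, optional ``mol_weight``,
    ``protein_id``, ``affinity_type``, ``affinity_value_nM``.  Ligands with
    unparseable SMILES are rejected (their interaction rows then drop out
    as unresolved in :func:`filter_interactions`).
    """
    from .chem import parse_molecule
    from .errors import ParseError

    df = pd.read_csv(path, sep="\t", dtype={"ligand_id": str, "protein_id": str})
    required = {"ligand_id", "smiles", "protein_id", "affinity_type", "affinity_value_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    molecules: dict[str, Molecule] = {}
    n_bad = 0
    for _, row in df.drop_duplicates("ligand_id").iterrows():
        mw = row.get("mol_weight")
        mw = float(mw) if mw is not None and np.isfinite(mw) else None
        try:
            molecules[row.ligand_id] = parse_molecule(row.smiles, row.ligand_id, mw)
        except ParseError:
            n_bad += 1
    if n_bad:
        log.warning("%s: rejected %d ligands with unparseable SMILES", path, n_bad)
    records = [
        InteractionRecord(
            ligand_id=row.ligand_id,
            protein_id=row.protein_id,
            affinity_type=str(row.affinity_type),
            affinity_value_nM=float(row.affinity_value_nM),
        )
        for row in df.itertuples()
    ]
    return records, molecules


def write_interactions_tsv(
    records: list[InteractionRecord],
    molecules: dict[str, Molecule],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("ligand_id\tsmiles\tmol_weight\tprotein_id\taffinity_type\taffinity_value_nM\n")
        for rec in records:
            mol = molecules[rec.ligand_id]
            fh.write(
                f"{rec.ligand_id}\t{mol.smiles}\t{mol.mol_weight:.3f}\t"
                f"{rec.protein_id}\t{rec.affinity_type}\t{rec.affinity_value_nM:.6g}\n"
            )


def read_fasta(path: str | Path, families: dict[str, str] | None = None) -> dict[str, ProteinRecord]:
    proteins = {}
    for seq in SeqIO.parse(str(path), "fasta"):
        pid = seq.id
        proteins[pid] = ProteinRecord(
            protein_id=pid,
            sequence=str(seq.seq),
            family=(families or {}).get(pid),
        )
    return proteins


def write_fasta(proteins: dict[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid].sequence}\n")


def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square distance matrix: labelled TSV or PHYLIP-style.

    PHYLIP-style files start with the item count on the first line and have
    ``id d1 d2 ...`` rows; the TSV dialect has a header row of ids and the
    id repeated in the first column.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():  # PHYLIP
        n = int(first[0])
        ids, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return ids, np.asarray(rows)
    header = lines[0].split("\t")
    ids = header[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append([float(x) for x in parts[1:]])
    return ids, np.asarray(rows)


def write_distance_matrix(ids: list[str], values: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, pid in enumerate(ids):
            fh.write(pid + "\t" + "\t".join(f"{v:.6f}" for v in values[i]) + "\n")


def write_profiles_tsv(profiles: dict[str, ClusterProfile], path: str | Path) -> None:
    """Sparse export: one (protein_id, cluster_id) row per set bit."""
    with open(path, "w") as fh:
        fh.write("protein_id\tcluster_index\n")
        for pid in sorted(profiles):
            for k in sorted(profiles[pid].on_clusters()):
                fh.write(f"{pid}\t{k}\n")
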