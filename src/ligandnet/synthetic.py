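"""Synthetic fixtures: ligand libraries with planted clusters, interaction
tables with planted protein communities, and active/decoy screening sets.

Ligands are real molecules: each planted cluster is one rigid scaffold
decorated with small substituents, so within-cluster fingerprint Tanimoto
is high and between-cluster similarity low.  The generator measures the
achieved margins and resamples decorations when they are not met — the
similarity of decorated scaffolds cannot be predicted analytically.

Proteins are grouped into communities; each community binds one
characteristic block of ligand clusters (with optional bit-flip noise), and
a companion sequence set makes sequence similarity high inside communities.
This plants the same community structure into both the ligand-cluster and
the sequence view of the proteins, which is what the network-comparison
stages are tested against.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import Molecule, fingerprint, parse_molecule, tanimoto, write_smi
from .errors import GenerationFailed
from .protein_space import (
    InteractionRecord,
    ProteinRecord,
    write_distance_matrix,
    write_fasta,
    write_interactions_tsv,
)
from .screen import ScreenSet, write_screen_sets

log = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "LigandLibrary",
    "SyntheticInteractions",
    "SCAFFOLD_TEMPLATES",
    "SUBSTITUENTS",
    "make_ligand_library",
    "make_interaction_table",
    "make_screen_sets",
    "make_evaluation_queries",
    "write_synthetic_inputs",
]

# Rigid, mutually dissimilar cores with one decoration site {R}.  Chosen so
# that decorated members of one core stay above ~0.55 pairwise Tanimoto
# (hashed path fingerprints) while cross-core pairs stay below ~0.4.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "O=C1CC(c2ccc({R})cc2)Oc2ccccc21",
    "O=C(Nc1ccc2c(c1)OCO2)C{R}",
    "c1ccc2c(c1)nnn2Cc1ccc({R})cc1",
    "c1ccc2nc(N3CCN({R})CC3)ccc2c1",
    "CC1=CC(=O)N(c2ccc({R})cc2)N1",
    "CC(NC(=O)c1cnn(C)c1)c1ccc({R})cc1",
    "C1CN(CCN1C(=O)C{R})c1ccccc1",
    "c1ccc(-c2nc3cc({R})ccc3s2)cc1",
    "CC1CC(=O)N(c2ncc({R})s2)C1",
    "O=C(N1CCCC1)c1ccc({R})cc1F",
    "O=C(Nc1ccccn1)c1cc({R})ccc1Cl",
    "c1ccc(-n2cnc3cc({R})ccc32)cc1",
    "O=C(Nc1ccccc1)c1ccc({R})cn1",
    "O=C1N(c2ccc({R})cc2)CCN1c1ccccn1",
    "O=S(=O)(Nc1ccc({R})cc1)c1cccc2nsnc12",
    "CC(=O)N1CCC(Nc2ccc({R})cc2)CC1",
    "c1ccc(-c2noc(CN3CCOCC3)n2)c({R})c1",
    "O=C1NC(=S)NC(c2ccc({R})cc2)C1C",
    "CN(Cc1ccc({R})cc1)C(=O)c1ccno1",
    "O=C(NCC1CCCO1)c1ccc({R})nc1",
    "c1cc({R})ccc1N1CCOC(Cn2ccnc2)C1",
    "CC(C)(C)OC(=O)N1CCC(Oc2ccc({R})cc2)C1",
    "CSc1nc(-c2ccc({R})cc2)cc(C)n1",
    "O=C(NCc1cccnc1)C1CCN(Cc2ccc({R})cc2)C1",
    "Cn1cnc(S(=O)(=O)Nc2ccc({R})cc2)n1",
    "CC1COc2c(N3CCN(C)CC3)c({R})cc3c(=O)ccn1c23",
    "Clc1ccc(N2CCN(Cc3ccc({R})cc3)CC2)nn1",
)

# Small decorations; kept light so the core dominates the fingerprint.
SUBSTITUENTS: tuple[str, ...] = (
    "[H]", "C", "F", "Cl", "Br", "O", "N", "OC", "NC", "CC", "CO", "C#N",
    "CCC", "OCC", "CCO", "NCC", "C(C)C", "CC#N", "C=C", "CCF", "N(C)C",
    "OC(C)C", "CF", "SC",
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Knobs of the synthetic study conditions.

    ``within_cluster_similarity`` and ``between_cluster_similarity`` are the
    intended Tanimoto levels inside and across planted ligand clusters; the
    generator enforces that the measured within-mean clears the between-mean
    by half the configured gap.

    The defaults give each of the 4 protein communities a characteristic
    block of 3 ligand clusters.  A community distinguished by a single
    cluster would be degenerate — one profile-noise flip then bridges two
    communities at Jaccard 0.5 — so community structure is only planted
    with several chemotypes per community.
    """

    n_clusters: int = 12
    ligands_per_cluster: int = 10
    n_proteins: int = 48
    n_communities: int = 4
    within_cluster_similarity: float = 0.8
    between_cluster_similarity: float = 0.1
    profile_noise: float = 0.02
    member_binding_prob: float = 0.7
    weak_record_fraction: float = 0.1
    seq_length: int = 200
    seq_mutation_rate: float = 0.02
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self):
        for name in ("within_cluster_similarity", "between_cluster_similarity",
                     "profile_noise", "member_binding_prob", "weak_record_fraction",
                     "seq_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_clusters", "ligands_per_cluster", "n_proteins",
                     "n_communities", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_clusters > len(SCAFFOLD_TEMPLATES):
            raise ValueError(
                f"at most {len(SCAFFOLD_TEMPLATES)} planted clusters supported"
            )
        if self.ligands_per_cluster > len(SUBSTITUENTS):
            raise ValueError(
                f"at most {len(SUBSTITUENTS)} ligands per cluster supported"
            )


@dataclass
class LigandLibrary:
    """Planted-cluster ligand set with its generation provenance."""

    molecules: list[Molecule]
    labels: dict[str, int]                      # ligand_id -> planted cluster
    template_index: dict[int, int]              # planted cluster -> scaffold index
    used_substituents: dict[int, list[str]]     # planted cluster -> decorations


def _decorate(template: str, substituent: str, ligand_id: str) -> Molecule:
    return parse_molecule(template.format(R=substituent), ligand_id)


def _similarity_margins(molecules: list[Molecule], labels: dict[str, int]) -> tuple[float, float]:
    fps = {m.ligand_id: fingerprint(m) for m in molecules}
    within, between = [], []
    for a, b in itertools.combinations(molecules, 2):
        s = tanimoto(fps[a.ligand_id], fps[b.ligand_id])
        (within if labels[a.ligand_id] == labels[b.ligand_id] else between).append(s)
    return (
        float(np.mean(within)) if within else 1.0,
        float(np.mean(between)) if between else 0.0,
    )


def make_ligand_library(cfg: SynthConfig) -> LigandLibrary:
    """Decorated-scaffold library with one scaffold per planted cluster.

    Deterministic given ``cfg.seed``.  Raises :class:`GenerationFailed` when
    the within/between similarity margin cannot be reached after
    ``cfg.max_retries`` redecorations.
    """
    rng = np.random.default_rng(cfg.seed)
    template_ids = rng.choice(len(SCAFFOLD_TEMPLATES), cfg.n_clusters, replace=False)
    required_gap = 0.5 * (cfg.within_cluster_similarity - cfg.between_cluster_similarity)
    for attempt in range(cfg.max_retries):
        molecules: list[Molecule] = []
        labels: dict[str, int] = {}
        used: dict[int, list[str]] = {}
        for ci, ti in enumerate(template_ids.tolist()):
            subs = rng.choice(len(SUBSTITUENTS), cfg.ligands_per_cluster, replace=False)
            used[ci] = [SUBSTITUENTS[s] for s in subs]
            for j, sub in enumerate(used[ci]):
                lid = f"LIG{ci:02d}_{j:02d}"
                molecules.append(_decorate(SCAFFOLD_TEMPLATES[ti], sub, lid))
                labels[lid] = ci
        if cfg.n_clusters == 1 or cfg.ligands_per_cluster == 1:
            break
        w_mean, b_mean = _similarity_margins(molecules, labels)
        if w_mean >= b_mean + required_gap:
            break
        log.info("library attempt %d: within %.3f / between %.3f below margin; resampling",
                 attempt + 1, w_mean, b_mean)
    else:
        raise GenerationFailed(
            f"similarity margins unreachable after {cfg.max_retries} attempts"
        )
    return LigandLibrary(
        molecules=molecules,
        labels=labels,
        template_index={ci: int(ti) for ci, ti in enumerate(template_ids.tolist())},
        used_substituents=used,
    )


@dataclass
class SyntheticInteractions:
    """Interaction table with planted protein communities and sequences."""

    records: list[InteractionRecord]
    molecules: dict[str, Molecule]
    proteins: dict[str, ProteinRecord]
    protein_communities: dict[str, int]
    distance_ids: list[str]
    distances: np.ndarray
    protein_pathways: dict[str, frozenset[str]]
    protein_diseases: dict[str, frozenset[str]]
    cluster_adverse_reactions: dict[int, frozenset[str]]


def make_interaction_table(
    cfg: SynthConfig,
    library: LigandLibrary,
) -> SyntheticInteractions:
    """Plant protein communities into cluster-binding profiles and sequences.

    Clusters are split into ``n_communities`` contiguous blocks; a protein
    binds members of every cluster of its community's block (each member
    with probability ``member_binding_prob``, at least one), with
    per-cluster bit flips at rate ``profile_noise``.  Strong interactions
    get affinities at or below 10 uM; an extra ``weak_record_fraction`` of
    off-profile records with affinities above 10 uM exercises the filters.
    Protein sequences share a random community base sequence with point
    mutations, so within-community sequence distance is small.
    """
    if cfg.n_clusters < cfg.n_communities:
        raise GenerationFailed("need at least one ligand cluster per community")
    rng = np.random.default_rng([cfg.seed, 1])
    members_of: dict[int, list[str]] = {}
    for lid, ci in sorted(library.labels.items()):
        members_of.setdefault(ci, []).append(lid)
    blocks = [list(b) for b in np.array_split(np.arange(cfg.n_clusters), cfg.n_communities)]

    protein_ids = [f"PROT{i:03d}" for i in range(cfg.n_proteins)]
    communities = {pid: i % cfg.n_communities for i, pid in enumerate(protein_ids)}
    affinity_types = np.asarray(["Ki", "Kd", "EC50", "IC50"])

    records: list[InteractionRecord] = []
    for pid in protein_ids:
        block = set(int(c) for c in blocks[communities[pid]])
        bound: set[int] = set()
        for ci in range(cfg.n_clusters):
            in_block = ci in block
            if rng.random() < cfg.profile_noise:
                in_block = not in_block
            if in_block:
                bound.add(ci)
        if not bound:
            bound.add(int(min(block)))
        for ci in sorted(bound):
            chosen = [m for m in members_of[ci] if rng.random() < cfg.member_binding_prob]
            if not chosen:
                chosen = [members_of[ci][int(rng.integers(len(members_of[ci])))]]
            for lid in chosen:
                records.append(
                    InteractionRecord(
                        ligand_id=lid,
                        protein_id=pid,
                        affinity_type=str(rng.choice(affinity_types)),
                        affinity_value_nM=float(min(10.0 ** rng.uniform(0, 4), 10_000.0)),
                    )
                )

    n_weak = int(round(cfg.weak_record_fraction * len(records)))
    all_ligands = sorted(library.labels)
    for _ in range(n_weak):
        records.append(
            InteractionRecord(
                ligand_id=all_ligands[int(rng.integers(len(all_ligands)))],
                protein_id=protein_ids[int(rng.integers(len(protein_ids)))],
                affinity_type=str(rng.choice(affinity_types)),
                affinity_value_nM=float(10.0 ** rng.uniform(4.01, 6.0)),
            )
        )

    # community base sequences with per-protein point mutations
    aa = np.asarray(list(_AMINO_ACIDS))
    bases = {
        c: rng.integers(len(aa), size=cfg.seq_length) for c in range(cfg.n_communities)
    }
    seq_arrays: dict[str, np.ndarray] = {}
    proteins: dict[str, ProteinRecord] = {}
    for pid in protein_ids:
        seq = bases[communities[pid]].copy()
        mutate = rng.random(cfg.seq_length) < cfg.seq_mutation_rate
        seq[mutate] = rng.integers(len(aa), size=int(mutate.sum()))
        seq_arrays[pid] = seq
        proteins[pid] = ProteinRecord(
            protein_id=pid,
            sequence="".join(aa[seq]),
            family=f"FAM{communities[pid]}",
        )

    ids = sorted(protein_ids)
    S = np.stack([seq_arrays[p] for p in ids])
    distances = np.mean(S[:, None, :] != S[None, :, :], axis=2)
    np.fill_diagonal(distances, 0.0)

    pathways = {pid: frozenset({f"PW{communities[pid]}"}) for pid in protein_ids}
    diseases = {pid: frozenset({f"DIS{communities[pid]}"}) for pid in protein_ids}
    adrs = {
        ci: frozenset(
            f"ADR{int(x)}" for x in rng.choice(20, size=int(rng.integers(1, 4)), replace=False)
        )
        for ci in range(cfg.n_clusters)
    }
    return SyntheticInteractions(
        records=records,
        molecules={m.ligand_id: m for m in library.molecules},
        proteins=proteins,
        protein_communities=communities,
        distance_ids=ids,
        distances=distances,
        protein_pathways=pathways,
        protein_diseases=diseases,
        cluster_adverse_reactions=adrs,
    )


def make_screen_sets(
    cfg: SynthConfig,
    n_targets: int = 5,
    scaffolds_per_target: int = 3,
    actives_per_scaffold: int = 12,
    n_decoys: int = 60,
) -> list[ScreenSet]:
    """DUD-style benchmark sets: actives share scaffolds, decoys do not.

    Target ``t`` draws its actives from ``scaffolds_per_target`` dedicated
    scaffolds (so every target has at least 30 actives at the defaults) and
    its decoys from scaffolds belonging to other targets — same size range,
    unrelated core.
    """
    need = n_targets * scaffolds_per_target
    if need > len(SCAFFOLD_TEMPLATES):
        raise GenerationFailed(
            f"{need} scaffolds requested, only {len(SCAFFOLD_TEMPLATES)} available"
        )
    if actives_per_scaffold > len(SUBSTITUENTS):
        raise GenerationFailed("not enough substituents per scaffold")
    rng = np.random.default_rng([cfg.seed, 2])
    order = rng.permutation(len(SCAFFOLD_TEMPLATES))
    sets = []
    for t in range(n_targets):
        own = order[t * scaffolds_per_target : (t + 1) * scaffolds_per_target]
        others = [s for s in order.tolist() if s not in set(own.tolist())]
        actives = []
        for si, scaffold in enumerate(own.tolist()):
            subs = rng.choice(len(SUBSTITUENTS), actives_per_scaffold, replace=False)
            for j, s in enumerate(subs.tolist()):
                actives.append(
                    _decorate(
                        SCAFFOLD_TEMPLATES[scaffold],
                        SUBSTITUENTS[s],
                        f"T{t}_ACT_{si}_{j}",
                    )
                )
        decoys = []
        combos = [(s, u) for s in others for u in range(len(SUBSTITUENTS))]
        pick = rng.choice(len(combos), size=n_decoys, replace=False)
        for j, c in enumerate(pick.tolist()):
            scaffold, u = combos[c]
            decoys.append(
                _decorate(SCAFFOLD_TEMPLATES[scaffold], SUBSTITUENTS[u], f"T{t}_DEC_{j}")
            )
        sets.append(ScreenSet(target_id=f"target{t}", actives=actives, decoys=decoys))
    return sets


def make_evaluation_queries(
    cfg: SynthConfig,
    library: LigandLibrary,
    interactions: SyntheticInteractions,
    queries_per_cluster: int = 3,
) -> list[tuple[Molecule, frozenset[str]]]:
    """Held-out query molecules with their true protein sets.

    Each query decorates a library scaffold with a substituent the library
    did not use, and its true proteins are the targets that bind the
    corresponding planted cluster — new ligands of known chemotypes, the
    situation the prospective-evaluation protocol emulates.
    """
    cluster_targets: dict[int, set[str]] = {}
    for rec in interactions.records:
        ci = library.labels.get(rec.ligand_id)
        if ci is not None and rec.affinity_value_nM <= 10_000.0:
            cluster_targets.setdefault(ci, set()).add(rec.protein_id)
    rng = np.random.default_rng([cfg.seed, 3])
    queries = []
    for ci, ti in sorted(library.template_index.items()):
        unused = [s for s in SUBSTITUENTS if s not in set(library.used_substituents[ci])]
        if not unused or not cluster_targets.get(ci):
            continue
        take = rng.choice(len(unused), min(queries_per_cluster, len(unused)), replace=False)
        for j, u in enumerate(take.tolist()):
            mol = _decorate(SCAFFOLD_TEMPLATES[ti], unused[u], f"QRY{ci:02d}_{j}")
            queries.append((mol, frozenset(cluster_targets[ci])))
    return queries


def write_synthetic_inputs(
    directory: str | Path,
    library: LigandLibrary,
    interactions: SyntheticInteractions,
    sets: list[ScreenSet] | None = None,
) -> None:
    """Emit every file dialect the rest of the pipeline consumes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_smi(library.molecules, d / "ligands.smi")
    with open(d / "planted_ligand_clusters.tsv", "w") as fh:
        fh.write("ligand_id\tplanted_cluster\n")
        for lid in sorted(library.labels):
            fh.write(f"{lid}\t{library.labels[lid]}\n")
    write_interactions_tsv(interactions.records, interactions.molecules,
                           d / "interactions.tsv")
    write_fasta(interactions.proteins, d / "proteins.fasta")
    write_distance_matrix(interactions.distance_ids, interactions.distances,
                          d / "sequence_distances.tsv")
    with open(d / "protein_families.tsv", "w") as fh:
        fh.write("protein_id\tfamily\n")
        for pid in sorted(interactions.proteins):
            fh.write(f"{pid}\t{interactions.proteins[pid].family}\n")
    with open(d / "protein_pathways.tsv", "w") as fh:
        fh.write("protein_id\tpathway_id\n")
        for pid in sorted(interactions.protein_pathways):
            for pw in sorted(interactions.protein_pathways[pid]):
                fh.write(f"{pid}\t{pw}\n")
    if sets is not None:
        write_screen_sets(sets, d / "screen_sets")
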