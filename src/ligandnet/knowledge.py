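"""The multi-target query layer: exemplar search over the knowledge base.

The knowledge base holds ligand clusters with exemplar fingerprints, the
protein target range of each cluster, and optional annotation maps
(protein -> pathways, protein -> diseases, cluster -> adverse reactions).
A query molecule is compared against cluster exemplars only; the target
sets of the top-ranked clusters accumulate into the query's predicted
protein range.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import defaults
from .chem import (
    Fingerprint,
    Molecule,
    fingerprint,
    read_fingerprints,
    tanimoto,
    write_fingerprints,
)
from .clustering import LigandCluster, read_clusters_tsv, write_clusters_tsv
from .errors import UnknownIdentifier
from .protein_space import InteractionRecord

__all__ = [
    "KnowledgeBase",
    "QueryResult",
    "PredictionEvaluation",
    "build_knowledge_base",
    "query_similar_clusters",
    "conditional_search",
    "evaluate_predictions",
    "save_knowledge_base",
    "load_knowledge_base",
]


@dataclass
class KnowledgeBase:
    """Clusters, exemplar fingerprints, target ranges and annotations."""

    clusters: list[LigandCluster]
    exemplar_fps: dict[int, Fingerprint]
    cluster_targets: dict[int, frozenset[str]]
    protein_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    protein_diseases: dict[str, frozenset[str]] = field(default_factory=dict)
    cluster_adverse_reactions: dict[int, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for c in self.clusters:
            if c.cluster_id not in self.exemplar_fps:
                raise ValueError(f"cluster {c.cluster_id} has no exemplar fingerprint")
            if not self.cluster_targets.get(c.cluster_id):
                raise ValueError(f"cluster {c.cluster_id} has no target")

    @property
    def proteins(self) -> frozenset[str]:
        out: set[str] = set()
        for targets in self.cluster_targets.values():
            out |= targets
        return frozenset(out)

    def pathway_members(self, pathway: str) -> frozenset[str]:
        return frozenset(
            p for p, pws in self.protein_pathways.items() if pathway in pws
        )


@dataclass
class QueryResult:
    """Ranked exemplar hits with accumulated protein ranges."""

    ranked: list[tuple[int, float]]            # (cluster_id, similarity), best first
    accumulated_targets: list[frozenset[str]]  # entry i: union over top-(i+1)

    def __post_init__(self):
        sims = [s for _, s in self.ranked]
        assert all(a >= b for a, b in zip(sims, sims[1:])), "similarities must be sorted"


def build_knowledge_base(
    clusters: list[LigandCluster],
    fps: dict[str, Fingerprint],
    records: list[InteractionRecord],
    protein_pathways: dict[str, frozenset[str]] | None = None,
    protein_diseases: dict[str, frozenset[str]] | None = None,
    cluster_adverse_reactions: dict[int, frozenset[str]] | None = None,
) -> KnowledgeBase:
    """Assemble the knowledge base from clustering and filtered interactions.

    A cluster's target range is the union of the targets of its member
    ligands; clusters without any target are dropped.
    """
    ligand_targets: dict[str, set[str]] = {}
    for rec in records:
        ligand_targets.setdefault(rec.ligand_id, set()).add(rec.protein_id)
    kept = []
    cluster_targets: dict[int, frozenset[str]] = {}
    exemplar_fps: dict[int, Fingerprint] = {}
    for c in clusters:
        targets: set[str] = set()
        for m in c.member_ids:
            targets |= ligand_targets.get(m, set())
        if not targets:
            continue
        kept.append(c)
        cluster_targets[c.cluster_id] = frozenset(targets)
        exemplar_fps[c.cluster_id] = fps[c.exemplar_id]
    return KnowledgeBase(
        clusters=kept,
        exemplar_fps=exemplar_fps,
        cluster_targets=cluster_targets,
        protein_pathways=dict(protein_pathways or {}),
        protein_diseases=dict(protein_diseases or {}),
        cluster_adverse_reactions=dict(cluster_adverse_reactions or {}),
    )


def query_similar_clusters(
    query: Molecule | Fingerprint,
    kb: KnowledgeBase,
    k: int = defaults.TOP_K,
) -> QueryResult:
    """Rank clusters by query-exemplar Tanimoto, best first.

    Ties break toward the lower cluster id.  ``accumulated_targets[i]`` is
    the union of the target ranges of the top ``i+1`` clusters, so it can
    only grow with rank.
    """
    if not kb.clusters:
        raise ValueError("empty knowledge base")
    qfp = query if isinstance(query, Fingerprint) else fingerprint(query)
    scored = sorted(
        ((cid, tanimoto(qfp, fp)) for cid, fp in kb.exemplar_fps.items()),
        key=lambda t: (-t[1], t[0]),
    )[: min(k, len(kb.exemplar_fps))]
    accumulated: list[frozenset[str]] = []
    so_far: set[str] = set()
    for cid, _ in scored:
        so_far |= kb.cluster_targets[cid]
        accumulated.append(frozenset(so_far))
    return QueryResult(ranked=scored, accumulated_targets=accumulated)


def conditional_search(
    kb: KnowledgeBase,
    include_proteins: set[str] | None = None,
    exclude_proteins: set[str] | None = None,
    include_pathways: set[str] | None = None,
    exclude_pathways: set[str] | None = None,
    any_include: bool = False,
) -> set[int]:
    """Clusters whose target range satisfies include/exclude conditions.

    Each include term must be hit (AND semantics; ``any_include`` switches
    to OR): a protein term is hit when the cluster targets that protein, a
    pathway term when the cluster targets any protein of the pathway.  No
    exclude term may be hit.  Empty conditions return every cluster.

    Raises
    ------
    UnknownIdentifier
        For proteins or pathways absent from the knowledge base.
    """
    include_proteins = set(include_proteins or ())
    exclude_proteins = set(exclude_proteins or ())
    include_pathways = set(include_pathways or ())
    exclude_pathways = set(exclude_pathways or ())

    known_pathways: set[str] = set()
    for pws in kb.protein_pathways.values():
        known_pathways |= pws
    unknown = (
        (include_proteins | exclude_proteins) - kb.proteins
    ) | ((include_pathways | exclude_pathways) - known_pathways)
    if unknown:
        raise UnknownIdentifier(unknown)

    include_terms = [frozenset({p}) for p in sorted(include_proteins)]
    include_terms += [kb.pathway_members(pw) for pw in sorted(include_pathways)]
    exclude_terms = [frozenset({p}) for p in sorted(exclude_proteins)]
    exclude_terms += [kb.pathway_members(pw) for pw in sorted(exclude_pathways)]

    result: set[int] = set()
    for cid, targets in kb.cluster_targets.items():
        hit = [bool(targets & term) for term in include_terms]
        if include_terms and not (any(hit) if any_include else all(hit)):
            continue
        if any(targets & term for term in exclude_terms):
            continue
        result.add(cid)
    return result


@dataclass
class PredictionEvaluation:
    """Per-rank accumulated hits and query-exemplar similarity summaries."""

    n_interactions: int
    hits_at_rank: list[int]              # cumulative, index r-1 = hits within top r
    rank_similarities: list[list[float]] # similarities observed at each rank
    k: int

    @property
    def hit_rate_at_rank(self) -> list[float]:
        return [h / self.n_interactions for h in self.hits_at_rank]

    def median_similarity(self, rank: int) -> float:
        return statistics.median(self.rank_similarities[rank - 1])


def evaluate_predictions(
    new_interactions: list[tuple[Molecule, frozenset[str]]],
    kb: KnowledgeBase,
    k: int = defaults.TOP_K,
) -> PredictionEvaluation:
    """Check whether new interactions fall in accumulated protein ranges.

    An interaction counts as a hit at rank ``r`` when any of its true
    proteins appears in the union of the top-``r`` clusters' targets;
    counts therefore accumulate monotonically from rank 1 to ``k``.
    """
    hits = np.zeros(k, dtype=int)
    rank_similarities: list[list[float]] = [[] for _ in range(k)]
    for query, true_proteins in new_interactions:
        res = query_similar_clusters(query, kb, k=k)
        for r, (cid, sim) in enumerate(res.ranked):
            rank_similarities[r].append(sim)
        hit_rank = None
        for r, acc in enumerate(res.accumulated_targets):
            if true_proteins & acc:
                hit_rank = r
                break
        if hit_rank is not None:
            hits[hit_rank:] += 1
    return PredictionEvaluation(
        n_interactions=len(new_interactions),
        hits_at_rank=hits.tolist(),
        rank_similarities=rank_similarities,
        k=k,
    )


# ---------------------------------------------------------------------------
# serialization: a directory of TSVs plus a manifest


def _write_map_tsv(path: Path, mapping: dict, key_name: str, value_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{key_name}\t{value_name}\n")
        for key in sorted(mapping, key=str):
            for value in sorted(mapping[key]):
                fh.write(f"{key}\t{value}\n")


def _read_map_tsv(path: Path, key_type=str) -> dict:
    mapping: dict = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            mapping.setdefault(key_type(key), set()).add(value)
    return {k: frozenset(v) for k, v in mapping.items()}


def save_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_clusters_tsv(kb.clusters, d / "clusters.tsv")
    write_fingerprints(
        {str(cid): fp for cid, fp in kb.exemplar_fps.items()}, d / "exemplar_fps.tsv"
    )
    _write_map_tsv(d / "cluster_targets.tsv", kb.cluster_targets, "cluster_id", "protein_id")
    _write_map_tsv(d / "protein_pathways.tsv", kb.protein_pathways, "protein_id", "pathway_id")
    _write_map_tsv(d / "protein_diseases.tsv", kb.protein_diseases, "protein_id", "disease_id")
    _write_map_tsv(
        d / "cluster_adverse_reactions.tsv",
        kb.cluster_adverse_reactions,
        "cluster_id",
        "adverse_reaction_id",
    )
    manifest = {
        "n_clusters": len(kb.clusters),
        "n_proteins": len(kb.proteins),
        "fingerprint_bits": len(next(iter(kb.exemplar_fps.values()))),
        "files": [
            "clusters.tsv",
            "exemplar_fps.tsv",
            "cluster_targets.tsv",
            "protein_pathways.tsv",
            "protein_diseases.tsv",
            "cluster_adverse_reactions.tsv",
        ],
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_knowledge_base(directory: str | Path) -> KnowledgeBase:
    d = Path(directory)
    clusters = read_clusters_tsv(d / "clusters.tsv")
    manifest = json.loads((d / "manifest.json").read_text())
    n_bits = manifest.get("fingerprint_bits", 2048)
    exemplar_fps = {
        int(cid): fp
        for cid, fp in read_fingerprints(d / "exemplar_fps.tsv", n_bits=n_bits).items()
    }
    return KnowledgeBase(
        clusters=clusters,
        exemplar_fps=exemplar_fps,
        cluster_targets=_read_map_tsv(d / "cluster_targets.tsv", key_type=int),
        protein_pathways=_read_map_tsv(d / "protein_pathways.tsv"),
        protein_diseases=_read_map_tsv(d / "protein_diseases.tsv"),
        cluster_adverse_reactions=_read_map_tsv(
            d / "cluster_adverse_reactions.tsv", key_type=int
        ),
    )
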