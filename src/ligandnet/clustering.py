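"""Affinity-propagation clustering of ligands on a thresholded Tanimoto graph.

Only ligand pairs whose fingerprint Tanimoto exceeds a threshold (default
0.5) enter the similarity structure.  Affinity propagation is run per
connected component of that graph — ligands with no retained edge cannot
share an exemplar with anyone, so components are independent — and each
cluster is represented by the exemplar ligand the algorithm selects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from . import defaults
from .chem import Fingerprint

log = logging.getLogger(__name__)

__all__ = [
    "SimilarityEdgeList",
    "LigandCluster",
    "build_similarity_edges",
    "affinity_propagation",
    "ap_partition",
    "cluster_size_histogram",
    "write_clusters_tsv",
    "read_clusters_tsv",
    "write_clusters_json",
]


@dataclass
class SimilarityEdgeList:
    """Sparse upper-triangle similarity entries over a universe of item ids.

    Every stored similarity is strictly above ``threshold``; items without a
    single retained edge still appear in ``universe``.
    """

    entries: list[tuple[str, str, float]]
    universe: set[str]
    threshold: float = defaults.LIGAND_EDGE_THRESHOLD

    def __post_init__(self):
        for a, b, s in self.entries:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if s <= self.threshold:
                raise ValueError(f"edge ({a},{b}) similarity {s} not above {self.threshold}")
        ids = {i for a, b, _ in self.entries for i in (a, b)}
        if not ids <= self.universe:
            raise ValueError("edge endpoints missing from universe")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class LigandCluster:
    """An exemplar ligand plus the members it represents."""

    cluster_id: int
    exemplar_id: str
    member_ids: frozenset[str]
    avg_mol_weight: float = float("nan")

    def __post_init__(self):
        self.member_ids = frozenset(self.member_ids)
        if not self.member_ids:
            raise ValueError("empty cluster")
        if self.exemplar_id not in self.member_ids:
            raise ValueError(f"exemplar {self.exemplar_id!r} not among members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_similarity_edges(
    fps: dict[str, Fingerprint],
    threshold: float = defaults.LIGAND_EDGE_THRESHOLD,
) -> SimilarityEdgeList:
    """All-pairs Tanimoto, keeping pairs strictly above ``threshold``.

    The pair similarities are computed with one bit-matrix product, which is
    exactly the brute-force double loop in vector form.
    """
    if not fps:
        raise ValueError("no fingerprints supplied")
    ids = sorted(fps)
    lengths = {len(fps[i]) for i in ids}
    if len(lengths) > 1:
        raise ValueError(f"mixed fingerprint lengths: {sorted(lengths)}")
    bits = np.stack([fps[i].bits for i in ids]).astype(np.int32)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    entries = []
    ii, jj = np.nonzero(np.triu(sim > threshold, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        entries.append((ids[i], ids[j], float(sim[i, j])))
    return SimilarityEdgeList(entries=entries, universe=set(ids), threshold=threshold)


def ap_partition(
    S: np.ndarray,
    preference: float = defaults.AP_PREFERENCE,
    damping: float = defaults.AP_DAMPING,
    max_iter: int = defaults.AP_MAX_ITER,
    convergence_iter: int = defaults.AP_CONVERGENCE_ITER,
) -> tuple[np.ndarray, list[int]]:
    """Affinity propagation on a dense similarity matrix.

    Returns integer labels (0..k-1) and the exemplar row indices.  If the
    message passing fails to converge to any exemplar, every item becomes
    its own exemplar and a warning is emitted; the run never crashes.
    """
    n = S.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int), [0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = AffinityPropagation(
            affinity="precomputed",
            preference=preference,
            damping=damping,
            max_iter=max_iter,
            convergence_iter=convergence_iter,
            random_state=0,
        ).fit(S)
    centers = np.asarray(model.cluster_centers_indices_)
    if centers.size == 0:
        warnings.warn(
            f"affinity propagation found no exemplars on a {n}-item block; "
            "falling back to singletons",
            stacklevel=2,
        )
        return np.arange(n), list(range(n))
    return model.labels_.astype(int), [int(c) for c in centers]


def _connected_components(ids: list[str], entries) -> list[list[str]]:
    # union-find over the edge list; deterministic given sorted ids
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in entries:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return [sorted(comps[r]) for r in sorted(comps)]


def affinity_propagation(
    edges: SimilarityEdgeList,
    preference: float = defaults.AP_PREFERENCE,
    mol_weights: dict[str, float] | None = None,
    damping: float = defaults.AP_DAMPING,
    max_iter: int = defaults.AP_MAX_ITER,
    convergence_iter: int = defaults.AP_CONVERGENCE_ITER,
    missing_similarity: float = defaults.AP_MISSING_SIMILARITY,
) -> list[LigandCluster]:
    """Cluster every item of ``edges.universe`` exactly once.

    Affinity propagation runs independently on each connected component of
    the edge graph; pairs inside a component that fell below the edge
    threshold are imputed with ``missing_similarity`` (a large negative
    value, so they never pay to co-locate).  Items with no edge at all
    become singleton clusters with themselves as exemplar.

    When ``mol_weights`` is given, each cluster's average molecular weight
    is the mean over its members.
    """
    ids = sorted(edges.universe)
    sim: dict[tuple[str, str], float] = {}
    for a, b, s in edges.entries:
        key = (a, b) if a < b else (b, a)
        sim[key] = s

    clusters: list[tuple[str, frozenset[str]]] = []
    for comp in _connected_components(ids, edges.entries):
        if len(comp) == 1:
            clusters.append((comp[0], frozenset(comp)))
            continue
        n = len(comp)
        S = np.full((n, n), missing_similarity)
        np.fill_diagonal(S, 0.0)  # overwritten by the preference inside AP
        index = {c: k for k, c in enumerate(comp)}
        for (a, b), s in sim.items():
            if a in index and b in index:
                S[index[a], index[b]] = s
                S[index[b], index[a]] = s
        labels, centers = ap_partition(
            S, preference=preference, damping=damping,
            max_iter=max_iter, convergence_iter=convergence_iter,
        )
        for k, center in enumerate(centers):
            members = frozenset(comp[i] for i in np.flatnonzero(labels == k))
            clusters.append((comp[center], members))

    clusters.sort(key=lambda t: t[0])
    out = []
    for cid, (exemplar, members) in enumerate(clusters):
        amw = float("nan")
        if mol_weights is not None:
            amw = float(np.mean([mol_weights[m] for m in members]))
        out.append(LigandCluster(cluster_id=cid, exemplar_id=exemplar,
                                 member_ids=members, avg_mol_weight=amw))
    assigned = [m for c in out for m in c.member_ids]
    assert len(assigned) == len(set(assigned)) == len(edges.universe)
    return out


def cluster_size_histogram(clusters: list[LigandCluster]) -> dict[int, int]:
    """Number of clusters at each member count."""
    hist: dict[int, int] = {}
    for c in clusters:
        hist[c.size] = hist.get(c.size, 0) + 1
    return hist


def write_clusters_tsv(clusters: list[LigandCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\texemplar_id\tmember_id\n")
        for c in clusters:
            for m in sorted(c.member_ids):
                fh.write(f"{c.cluster_id}\t{c.exemplar_id}\t{m}\n")


def read_clusters_tsv(path: str | Path) -> list[LigandCluster]:
    rows: dict[int, tuple[str, set[str]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cid, exemplar, member = line.rstrip("\n").split("\t")
            rows.setdefault(int(cid), (exemplar, set()))[1].add(member)
    return [
        LigandCluster(cluster_id=cid, exemplar_id=ex, member_ids=frozenset(mem))
        for cid, (ex, mem) in sorted(rows.items())
    ]


def write_clusters_json(clusters: list[LigandCluster], path: str | Path) -> None:
    payload = [
        {
            "cluster_id": c.cluster_id,
            "exemplar_id": c.exemplar_id,
            "members": sorted(c.member_ids),
            "avg_mol_weight": None if np.isnan(c.avg_mol_weight) else c.avg_mol_weight,
        }
        for c in clusters
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
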