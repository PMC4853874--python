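"""Protein similarity networks, community detection and partition comparison.

Two networks are built over the same proteins: the ligand-cluster-based
network (LCBN, edges weighted by Jaccard similarity of cluster profiles)
and the sequence-based network (SBN, edges weighted by global sequence
similarity).  A "threshold" network keeps only edges above a display
threshold (default 0.25); the "integrate" network keeps every positive
similarity.  Communities come from affinity propagation on the similarity
matrix, or from optional external backends (infomap via python-igraph,
MCL via its executable), and partitions are compared with normalized
mutual information.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from . import defaults
from .clustering import ap_partition
from .errors import BackendUnavailable, EmptyOverlap
from .protein_space import SimilarityMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ProteinNetwork",
    "Partition",
    "build_network",
    "connected_components",
    "communities_ap",
    "communities_external",
    "available_backends",
    "nmi",
    "write_graphml",
    "write_sif",
    "write_partition_tsv",
]


@dataclass
class ProteinNetwork:
    """Weighted undirected protein graph above a similarity threshold."""

    graph: nx.Graph
    threshold: float
    kind: str  # "LCBN" or "SBN"

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def isolated(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree if d == 0)

    def edge_count(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Partition:
    """A community labelling of a node universe."""

    assignment: dict[str, int]
    method: str
    exemplars: dict[int, str] = field(default_factory=dict)

    def labels_for(self, nodes: list[str]) -> np.ndarray:
        return np.asarray([self.assignment[n] for n in nodes])

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def build_network(
    sim: SimilarityMatrix,
    threshold: float = defaults.NETWORK_EDGE_THRESHOLD,
    kind: str | None = None,
) -> ProteinNetwork:
    """Keep edges with similarity strictly above ``threshold``.

    Every protein remains a node; those left without an edge are flagged
    with the node attribute ``isolated`` and excluded from giant-component
    statistics downstream.
    """
    G = nx.Graph()
    G.add_nodes_from(sim.ids)
    n = len(sim.ids)
    iu, ju = np.nonzero(np.triu(sim.values > threshold, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        G.add_edge(sim.ids[i], sim.ids[j], weight=float(sim.values[i, j]))
    for node in G.nodes:
        G.nodes[node]["isolated"] = G.degree(node) == 0
    return ProteinNetwork(
        graph=G,
        threshold=threshold,
        kind=kind or ("LCBN" if sim.kind == "ligand_cluster" else "SBN"),
    )


def connected_components(net: ProteinNetwork, include_isolated: bool = True) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    if not include_isolated:
        comps = [c for c in comps if len(c) > 1]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def communities_ap(
    sim: SimilarityMatrix,
    preference: float = defaults.AP_PREFERENCE,
) -> Partition:
    """Affinity-propagation communities on the full similarity matrix.

    Runs the clustering module's message-passing engine on the full dense
    matrix — the integrate-network view, where a zero similarity is a real
    (maximally dissimilar) value rather than a missing one.  Proteins with
    no positive similarity to anybody are split off as singleton
    communities first; affinity propagation places the rest.
    """
    values = np.asarray(sim.values)
    off_diag = values - np.eye(len(sim.ids))
    connected = [i for i in range(len(sim.ids)) if off_diag[i].max() > 0.0]
    lonely = [i for i in range(len(sim.ids)) if off_diag[i].max() <= 0.0]
    assignment: dict[str, int] = {}
    exemplars: dict[int, str] = {}
    next_label = 0
    if len(connected) == 1:
        lonely = sorted(lonely + connected)
        connected = []
    if connected:
        sub = values[np.ix_(connected, connected)]
        labels, centers = ap_partition(sub, preference=preference)
        for pos, i in enumerate(connected):
            assignment[sim.ids[i]] = int(labels[pos])
        for k, c in enumerate(centers):
            exemplars[k] = sim.ids[connected[c]]
        next_label = len(centers)
    for i in lonely:
        assignment[sim.ids[i]] = next_label
        exemplars[next_label] = sim.ids[i]
        next_label += 1
    return Partition(assignment=assignment, method="AP", exemplars=exemplars)


def available_backends() -> list[str]:
    found = []
    try:
        import igraph  # noqa: F401

        found.append("infomap")
    except ImportError:
        pass
    if shutil.which("mcl"):
        found.append("mcl")
    return found


def communities_external(
    net: ProteinNetwork,
    method: str,
    inflation: float = 4.0,
) -> Partition:
    """Partition via an external backend: ``infomap`` or ``mcl``.

    infomap runs through python-igraph with default parameters; MCL shells
    out to the ``mcl`` executable with the given inflation.  A missing
    backend raises :class:`BackendUnavailable` so callers can skip it
    cleanly.
    """
    if method == "infomap":
        try:
            import igraph
        except ImportError as exc:
            raise BackendUnavailable("python-igraph is not installed") from exc
        nodes = net.nodes
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in net.graph.edges]
        weights = [net.graph[u][v]["weight"] for u, v in net.graph.edges]
        g = igraph.Graph(n=len(nodes), edges=edges)
        communities = g.community_infomap(edge_weights=weights or None)
        assignment = {nodes[i]: int(communities.membership[i]) for i in range(len(nodes))}
        return Partition(assignment=assignment, method="infomap")
    if method == "mcl":
        exe = shutil.which("mcl")
        if exe is None:
            raise BackendUnavailable("the mcl executable is not on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            abc = Path(tmp) / "graph.abc"
            out = Path(tmp) / "out.mcl"
            with open(abc, "w") as fh:
                for u, v, d in net.graph.edges(data=True):
                    fh.write(f"{u}\t{v}\t{d['weight']:.6f}\n")
            subprocess.run(
                [exe, str(abc), "--abc", "-I", str(inflation), "-o", str(out)],
                check=True,
                capture_output=True,
            )
            assignment: dict[str, int] = {}
            with open(out) as fh:
                for label, line in enumerate(fh):
                    for node in line.split():
                        assignment[node] = label
        next_label = max(assignment.values(), default=-1) + 1
        for node in net.nodes:  # mcl omits isolated nodes
            if node not in assignment:
                assignment[node] = next_label
                next_label += 1
        return Partition(assignment=assignment, method="mcl")
    raise ValueError(f"unknown backend {method!r}")


def nmi(a: Partition, b: Partition, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    Computed over the shared node universe (a warning is emitted when the
    universes differ).  ``average_method`` selects the normalizer:
    ``"arithmetic"`` (mean of the two label entropies, the default) or
    ``"max"``.

    Raises
    ------
    EmptyOverlap
        If the partitions share no nodes.
    """
    common = sorted(set(a.assignment) & set(b.assignment))
    if not common:
        raise EmptyOverlap("partitions share no nodes")
    if len(common) != len(a.assignment) or len(common) != len(b.assignment):
        warnings.warn(
            f"partitions compared on {len(common)} shared nodes "
            f"(of {len(a.assignment)} and {len(b.assignment)})",
            stacklevel=2,
        )
    return float(
        normalized_mutual_info_score(
            a.labels_for(common), b.labels_for(common), average_method=average_method
        )
    )


def write_graphml(net: ProteinNetwork, path: str | Path,
                  families: dict[str, str] | None = None) -> None:
    G = net.graph.copy()
    for node in G.nodes:
        G.nodes[node]["kind"] = net.kind
        if families and node in families:
            G.nodes[node]["family"] = families[node]
    nx.write_graphml(G, str(path))


def write_sif(net: ProteinNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\tsim\t{v}\n")
        for node in net.isolated:
            fh.write(f"{node}\n")


def write_partition_tsv(partitions: list[Partition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tmethod\tlabel\n")
        for part in partitions:
            for node in sorted(part.assignment):
                fh.write(f"{node}\t{part.method}\t{part.assignment[node]}\n")
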