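"""Protein networks, communities and normalized mutual information."""

import itertools
import math
import shutil

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from ligandnet.errors import BackendUnavailable, EmptyOverlap
from ligandnet.network import (
    Partition,
    available_backends,
    build_network,
    communities_ap,
    communities_external,
    connected_components,
    nmi,
    write_graphml,
    write_partition_tsv,
    write_sif,
)
from ligandnet.protein_space import SimilarityMatrix


def sim_matrix(ids, entries, kind="ligand_cluster"):
    n = len(ids)
    V = np.eye(n)
    index = {p: i for i, p in enumerate(ids)}
    for a, b, s in entries:
        V[index[a], index[b]] = V[index[b], index[a]] = s
    return SimilarityMatrix(ids=list(ids), values=V, kind=kind)


def nmi_entropy_oracle(x, y):
    """Direct summation over the contingency table, arithmetic normalizer."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    info = 0.0
    for a in set(x.tolist()):
        for b in set(y.tolist()):
            nab = np.sum((x == a) & (y == b))
            if nab:
                info += (nab / n) * math.log(
                    (nab / n) / ((np.sum(x == a) / n) * (np.sum(y == b) / n))
                )

    def entropy(z):
        return -sum(
            (np.sum(z == v) / n) * math.log(np.sum(z == v) / n) for v in set(z.tolist())
        )

    hx, hy = entropy(x), entropy(y)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    denom = (hx + hy) / 2
    return info / denom if denom else 0.0


class TestNetwork:
    def test_threshold_keeps_only_strictly_greater_edges(self):
        net = build_network(
            sim_matrix(["P", "Q", "R"], [("P", "Q", 0.3), ("P", "R", 0.2)]),
            threshold=0.25,
        )
        assert set(net.graph.edges) == {("P", "Q")}
        assert net.isolated == ["R"]

    def test_zero_threshold_keeps_all_positive(self):
        net = build_network(
            sim_matrix(["a", "b", "c"], [("a", "b", 0.1), ("a", "c", 0.2), ("b", "c", 0.3)]),
            threshold=0.0,
        )
        assert net.edge_count() == 3

    def test_edges_match_brute_force_filter_and_monotonicity(self):
        rng = np.random.default_rng(9)
        ids = [f"P{i:02d}" for i in range(30)]
        X = rng.random((30, 30))
        V = (X + X.T) / 2
        np.fill_diagonal(V, 1.0)
        sim = SimilarityMatrix(ids=ids, values=V, kind="sequence")
        prev_edges = None
        for threshold in (0.25, 0.5, 0.75):
            net = build_network(sim, threshold=threshold)
            expected = {
                tuple(sorted((ids[i], ids[j])))
                for i, j in itertools.combinations(range(30), 2)
                if V[i, j] > threshold
            }
            got = {tuple(sorted(e)) for e in net.graph.edges}
            assert got == expected
            if prev_edges is not None:
                assert len(got) <= prev_edges  # raising threshold never adds edges
            prev_edges = len(got)

    def test_components_ordered_by_size(self):
        net = build_network(
            sim_matrix(
                ["a", "b", "c", "d", "e"],
                [("a", "b", 0.9), ("c", "d", 0.9), ("c", "e", 0.9)],
            ),
            threshold=0.25,
        )
        comps = connected_components(net)
        assert [len(c) for c in comps] == [3, 2]
        assert comps[0] == {"c", "d", "e"}

    def test_isolated_nodes_are_singleton_components(self):
        net = build_network(sim_matrix(["a", "b", "c", "d", "e"], []), threshold=0.25)
        assert len(connected_components(net)) == 5
        assert connected_components(net, include_isolated=False) == []


class TestCommunitiesAP:
    def test_two_perfect_blocks_give_two_communities(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        entries = [
            (p, q, 0.9)
            for group in (["a1", "a2", "a3"], ["b1", "b2", "b3"])
            for p, q in itertools.combinations(group, 2)
        ]
        part = communities_ap(sim_matrix(ids, entries))
        assert part.n_communities == 2
        assert len({part.assignment[p] for p in ["a1", "a2", "a3"]}) == 1
        assert part.assignment["a1"] != part.assignment["b1"]

    def test_identity_matrix_gives_all_singletons(self):
        part = communities_ap(sim_matrix(["a", "b", "c", "d"], []))
        assert part.n_communities == 4

    def test_planted_communities_recovered_end_to_end(self, e2e):
        part = communities_ap(e2e.lcbn_sim)
        truth = [e2e.synth.protein_communities[p] for p in e2e.lcbn_sim.ids]
        pred = [part.assignment[p] for p in e2e.lcbn_sim.ids]
        assert normalized_mutual_info_score(truth, pred) >= 0.9


class TestExternalBackends:
    def _two_cliques(self):
        ids = [f"n{i}" for i in range(8)]
        entries = [
            (p, q, 0.9)
            for group in (ids[:4], ids[4:])
            for p, q in itertools.combinations(group, 2)
        ]
        return build_network(sim_matrix(ids, entries), threshold=0.25)

    def test_infomap_separates_disconnected_cliques(self):
        pytest.importorskip("igraph")
        part = communities_external(self._two_cliques(), "infomap")
        assert part.n_communities == 2

    def test_missing_backend_is_clean_error(self):
        net = self._two_cliques()
        if shutil.which("mcl") is None:
            assert "mcl" not in available_backends()
            with pytest.raises(BackendUnavailable):
                communities_external(net, "mcl")
        else:
            part = communities_external(net, "mcl", inflation=4.0)
            assert part.n_communities == 2

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            communities_external(self._two_cliques(), "louvain")


class TestNMI:
    def test_identical_partitions_score_one(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1}, "x")
        assert nmi(p, p) == pytest.approx(1.0)

    def test_constant_partition_scores_zero(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1}, "x")
        const = Partition({"a": 7, "b": 7, "c": 7, "d": 7}, "c")
        assert nmi(p, const) == pytest.approx(0.0)

    def test_six_node_worked_example(self):
        a = Partition({str(i): 0 if i <= 3 else 1 for i in range(1, 7)}, "a")
        b = Partition({str(i): 0 if i <= 2 else 1 for i in range(1, 7)}, "b")
        nodes = sorted(a.assignment)
        expected = nmi_entropy_oracle(a.labels_for(nodes), b.labels_for(nodes))
        assert nmi(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.47870, abs=1e-4)

    def test_symmetry_and_oracle_agreement_on_random_partitions(self):
        rng = np.random.default_rng(17)
        nodes = [f"n{i}" for i in range(30)]
        for _ in range(20):
            a = Partition(dict(zip(nodes, rng.integers(0, 4, 30).tolist())), "a")
            b = Partition(dict(zip(nodes, rng.integers(0, 5, 30).tolist())), "b")
            v = nmi(a, b)
            assert v == pytest.approx(nmi(b, a), abs=1e-12)
            assert v == pytest.approx(
                nmi_entropy_oracle(a.labels_for(nodes), b.labels_for(nodes)), abs=1e-9
            )

    def test_max_normalizer_flag(self):
        a = Partition({str(i): 0 if i <= 3 else 1 for i in range(1, 7)}, "a")
        b = Partition({str(i): 0 if i <= 2 else 1 for i in range(1, 7)}, "b")
        assert nmi(a, b, average_method="max") <= nmi(a, b, average_method="arithmetic")

    def test_disjoint_universes_raise_and_partial_overlap_warns(self):
        a = Partition({"a": 0, "b": 1}, "a")
        b = Partition({"c": 0, "d": 1}, "b")
        with pytest.raises(EmptyOverlap):
            nmi(a, b)
        c = Partition({"a": 0, "b": 1, "c": 0}, "c")
        with pytest.warns(UserWarning, match="shared nodes"):
            nmi(a, c)


class TestWriters:
    def test_graphml_sif_and_partition_files(self, tmp_path):
        net = build_network(
            sim_matrix(["P", "Q", "R"], [("P", "Q", 0.6)]), threshold=0.25
        )
        write_graphml(net, tmp_path / "net.graphml", families={"P": "kinase"})
        write_sif(net, tmp_path / "net.sif")
        part = communities_ap(sim_matrix(["P", "Q", "R"], [("P", "Q", 0.6)]))
        write_partition_tsv([part], tmp_path / "part.tsv")
        assert "kinase" in (tmp_path / "net.graphml").read_text()
        sif = (tmp_path / "net.sif").read_text()
        assert "P\tsim\tQ" in sif and "R" in sif
        lines = (tmp_path / "part.tsv").read_text().splitlines()
        assert lines[0] == "node_id\tmethod\tlabel" and len(lines) == 4
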