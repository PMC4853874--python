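"""Interaction filters, cluster profiles, protein similarity and promiscuity."""

import itertools

import numpy as np
import pytest

from ligandnet.chem import Molecule
from ligandnet.clustering import LigandCluster
from ligandnet.errors import EmptyResult, MatrixMalformed, UnclusteredLigand
from ligandnet.protein_space import (
    ClusterProfile,
    InteractionRecord,
    ProteinRecord,
    annotate_proteins,
    filter_interactions,
    jaccard_similarity_matrix,
    promiscuity_stats,
    read_distance_matrix,
    read_fasta,
    read_interactions_tsv,
    sequence_similarity_matrix,
    write_distance_matrix,
    write_fasta,
    write_interactions_tsv,
)


def rec(lig, prot, atype, value):
    return InteractionRecord(lig, prot, atype, value)


@pytest.fixture()
def toy_filter_data():
    ligands = {
        "LA": Molecule("LA", "CCO", 400.0),
        "LB": Molecule("LB", "CCO", 850.0),
        "LC": Molecule("LC", "CCO", 799.9),
    }
    proteins = {
        "PA": ProteinRecord("PA", "M" * 300),
        "PB": ProteinRecord("PB", "M" * 80),   # exactly 80: too short
        "PC": ProteinRecord("PC", "M" * 81),   # 81: long enough
    }
    records = [
        rec("LA", "PA", "Ki", 5_000),        # kept
        rec("LA", "PA", "IC50", 20_000),     # affinity (20 uM)
        rec("LB", "PA", "Kd", 100),          # ligand too heavy
        rec("LA", "PB", "EC50", 100),        # protein too short
        rec("LA", "PC", "IC50", 10_000),     # kept: cutoff is inclusive
        rec("LC", "PA", "Ki", 9_999),        # kept: 799.9 Da < 800
        rec("LA", "PA", "AC50", 100),        # unsupported affinity type
        rec("LZ", "PA", "Ki", 10),           # unknown ligand
        rec("LA", "PX", "Ki", 10),           # unknown protein
        rec("LA", "PA", "IC50", 10_000.1),   # just over the cutoff
        rec("LC", "PC", "EC50", 1),          # kept
        rec("LB", "PB", "Ki", 20_000),       # fails affinity first
    ]
    return records, ligands, proteins


class TestFilter:
    def test_toy_table_matches_hand_enumeration(self, toy_filter_data):
        records, ligands, proteins = toy_filter_data
        kept, report = filter_interactions(records, ligands, proteins)
        assert [(r.ligand_id, r.protein_id, r.affinity_type) for r in kept] == [
            ("LA", "PA", "Ki"),
            ("LA", "PC", "IC50"),
            ("LC", "PA", "Ki"),
            ("LC", "PC", "EC50"),
        ]
        assert report.as_dict() == {
            "n_input": 12,
            "unresolved_ligand": 1,
            "unresolved_protein": 1,
            "bad_affinity_type": 1,
            "affinity_rule": 3,
            "mol_weight_rule": 1,
            "seq_length_rule": 1,
            "n_kept": 4,
        }

    def test_idempotent(self, toy_filter_data):
        records, ligands, proteins = toy_filter_data
        once, _ = filter_interactions(records, ligands, proteins)
        twice, report = filter_interactions(once, ligands, proteins)
        assert twice == once
        assert report.n_kept == report.n_input == len(once)

    def test_empty_result_raises(self):
        with pytest.raises(EmptyResult):
            filter_interactions(
                [rec("LA", "PA", "Ki", 99_000)],
                {"LA": Molecule("LA", "CCO", 100.0)},
                {"PA": ProteinRecord("PA", "M" * 100)},
            )


CLUSTERS = [
    LigandCluster(0, "a", frozenset({"a", "b"})),
    LigandCluster(1, "c", frozenset({"c"})),
]


class TestAnnotate:
    def test_bits_follow_cluster_membership(self):
        records = [rec("a", "P", "Ki", 1), rec("b", "P", "Ki", 1), rec("c", "Q", "Ki", 1)]
        profiles = annotate_proteins(records, CLUSTERS)
        assert profiles["P"].bits.tolist() == [True, False]
        assert profiles["Q"].bits.tolist() == [False, True]

    def test_bit_is_cluster_level_not_ligand_level(self):
        records = [rec("a", "P", "Ki", 1), rec("b", "Q", "Ki", 1)]
        profiles = annotate_proteins(records, CLUSTERS)
        assert np.array_equal(profiles["P"].bits, profiles["Q"].bits)

    def test_unclustered_ligand_raises(self):
        with pytest.raises(UnclusteredLigand):
            annotate_proteins([rec("zz", "P", "Ki", 1)], CLUSTERS)


class TestJaccardMatrix:
    def test_worked_examples(self):
        profiles = {
            "P": ClusterProfile("P", np.array([1, 1, 0, 0], bool)),
            "Q": ClusterProfile("Q", np.array([0, 1, 1, 0], bool)),
            "R": ClusterProfile("R", np.array([1, 1, 0, 0], bool)),
            "S": ClusterProfile("S", np.array([0, 0, 0, 1], bool)),
        }
        sim = jaccard_similarity_matrix(profiles)
        assert sim.lookup("P", "Q") == pytest.approx(1 / 3)
        assert sim.lookup("P", "R") == 1.0
        assert sim.lookup("P", "S") == 0.0
        assert sim.kind == "ligand_cluster"

    def test_matches_set_oracle_on_random_profiles(self):
        rng = np.random.default_rng(5)
        profiles = {}
        for i in range(50):
            bits = rng.random(30) < 0.4
            if not bits.any():
                bits[0] = True
            profiles[f"P{i:02d}"] = ClusterProfile(f"P{i:02d}", bits)
        sim = jaccard_similarity_matrix(profiles)
        for a, b in itertools.combinations(sim.ids, 2):
            sa, sb = profiles[a].on_clusters(), profiles[b].on_clusters()
            assert sim.lookup(a, b) == pytest.approx(
                len(sa & sb) / len(sa | sb), abs=1e-12
            )


class TestSequenceMatrix:
    def test_one_minus_distance(self):
        D = np.array([[0.0, 0.78, 1.0], [0.78, 0.0, 0.5], [1.0, 0.5, 0.0]])
        sim = sequence_similarity_matrix(D, ["a", "b", "c"])
        assert sim.lookup("a", "b") == pytest.approx(0.22)
        assert sim.lookup("a", "c") == 0.0
        assert sim.lookup("a", "a") == 1.0
        assert sim.kind == "sequence"

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 0.5], [0.6, 0.0]]),      # asymmetric
            np.array([[0.1, 0.5], [0.5, 0.0]]),      # non-zero diagonal
            np.array([[0.0, 1.5], [1.5, 0.0]]),      # out of range
        ],
    )
    def test_malformed_matrices_rejected(self, bad):
        with pytest.raises(MatrixMalformed):
            sequence_similarity_matrix(bad, ["a", "b"])


class TestPromiscuity:
    def test_cluster_target_count_is_union_over_members(self):
        records = [rec("a", "P", "Ki", 1), rec("b", "Q", "Ki", 1), rec("c", "Q", "Ki", 1)]
        profiles = annotate_proteins(records, CLUSTERS)
        stats = promiscuity_stats(records, CLUSTERS, profiles)
        cluster0 = stats.cluster_stats.set_index("cluster_id").loc[0]
        assert cluster0.n_targets == 2  # a->P, b->Q
        singleton = stats.cluster_stats.set_index("cluster_id").loc[1]
        assert singleton.n_targets == 1

    def test_counts_match_brute_force_on_random_instance(self):
        rng = np.random.default_rng(11)
        ligands = [f"l{i:02d}" for i in range(50)]
        proteins = [f"p{i}" for i in range(10)]
        clusters = [
            LigandCluster(ci, members[0], frozenset(members))
            for ci, members in enumerate(np.array_split(np.array(ligands), 8))
            for members in [members.tolist()]
        ]
        records = []
        for lig in ligands:
            for prot in proteins:
                if rng.random() < 0.2:
                    records.append(rec(lig, prot, "Ki", 1))
        profiles = annotate_proteins(records, clusters)
        stats = promiscuity_stats(records, clusters, profiles)

        ligand_targets = {
            lig: {r.protein_id for r in records if r.ligand_id == lig} for lig in ligands
        }
        for row in stats.ligand_targets.itertuples():
            assert row.n_targets == len(ligand_targets[row.ligand_id])
        member_counts = {}
        for c in clusters:
            union = set().union(*(ligand_targets[m] for m in c.member_ids))
            member_counts[c.cluster_id] = (union, [len(ligand_targets[m]) for m in c.member_ids])
        for row in stats.cluster_stats.itertuples():
            union, per_member = member_counts[row.cluster_id]
            assert row.n_targets == len(union)
            assert max(per_member) <= row.n_targets <= sum(per_member)
        for row in stats.protein_stats.itertuples():
            assert row.n_clusters <= row.n_ligands

    def test_family_table_counts_distinct_clusters(self):
        records = [rec("a", "P", "Ki", 1), rec("c", "Q", "Ki", 1)]
        profiles = annotate_proteins(records, CLUSTERS)
        stats = promiscuity_stats(
            records, CLUSTERS, profiles, families={"P": "F1", "Q": "F1"}
        )
        assert stats.family_clusters.set_index("family").loc["F1", "n_clusters"] == 2


class TestFiles:
    def test_interactions_tsv_round_trip(self, tmp_path):
        molecules = {"a": Molecule("a", "CCO", 46.07), "b": Molecule("b", "CCN", 45.08)}
        records = [rec("a", "P", "Ki", 100.0), rec("b", "Q", "IC50", 2500.0)]
        path = tmp_path / "interactions.tsv"
        write_interactions_tsv(records, molecules, path)
        back_records, back_mols = read_interactions_tsv(path)
        assert back_records == records
        assert {m.smiles for m in back_mols.values()} == {"CCO", "CCN"}

    def test_fasta_round_trip_with_families(self, tmp_path):
        proteins = {
            "P1": ProteinRecord("P1", "MKTAYIAKQR"),
            "P2": ProteinRecord("P2", "MSSSSWLLLS"),
        }
        path = tmp_path / "prot.fasta"
        write_fasta(proteins, path)
        back = read_fasta(path, families={"P1": "kinase"})
        assert back["P1"].sequence == "MKTAYIAKQR"
        assert back["P1"].family == "kinase" and back["P2"].family is None

    def test_nonstandard_residues_mapped_to_x(self):
        assert ProteinRecord("P", "MKB*Z").sequence == "MKXXX"

    def test_distance_matrix_round_trip_and_phylip(self, tmp_path):
        ids = ["a", "b", "c"]
        D = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.7], [0.9, 0.7, 0.0]])
        path = tmp_path / "dist.tsv"
        write_distance_matrix(ids, D, path)
        back_ids, back = read_distance_matrix(path)
        assert back_ids == ids and np.allclose(back, D)

        phylip = tmp_path / "dist.phy"
        phylip.write_text(
            "3\na 0.0 0.2 0.9\nb 0.2 0.0 0.7\nc 0.9 0.7 0.0\n"
        )
        back_ids, back = read_distance_matrix(phylip)
        assert back_ids == ids and np.allclose(back, D)
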