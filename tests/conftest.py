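"""Shared fixtures: random fingerprints and session-scoped synthetic data."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from ligandnet.chem import Fingerprint, fingerprint
from ligandnet.clustering import (
    LigandCluster,
    affinity_propagation,
    build_similarity_edges,
)
from ligandnet.protein_space import (
    ClusterProfile,
    annotate_proteins,
    filter_interactions,
    jaccard_similarity_matrix,
    sequence_similarity_matrix,
)
from ligandnet.synthetic import (
    SynthConfig,
    make_interaction_table,
    make_ligand_library,
)

# sklearn warns when AP meets blocks of exactly tied similarities (identical
# synthetic profiles); that is expected on planted data
warnings.filterwarnings(
    "ignore", message="All samples have mutually equal similarities"
)


def random_fingerprint(rng: np.random.Generator, n_bits: int = 256, p: float = 0.3) -> Fingerprint:
    return Fingerprint(bits=rng.random(n_bits) < p)


def set_fingerprint(on_bits, n_bits: int = 64) -> Fingerprint:
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(on_bits)] = True
    return Fingerprint(bits=bits)


@pytest.fixture(scope="session")
def library5():
    """The planted 5-cluster x 10-ligand scaffold library."""
    return make_ligand_library(SynthConfig(n_clusters=5, ligands_per_cluster=10, seed=7))


@dataclass
class EndToEnd:
    cfg: SynthConfig
    library: object
    synth: object
    kept: list
    fps: dict
    clusters: list[LigandCluster]
    profiles: dict[str, ClusterProfile]
    lcbn_sim: object
    sbn_sim: object


@pytest.fixture(scope="session")
def e2e() -> EndToEnd:
    """Default-condition synthetic run up to the two similarity matrices."""
    cfg = SynthConfig(seed=7)
    library = make_ligand_library(cfg)
    synth = make_interaction_table(cfg, library)
    kept, _ = filter_interactions(synth.records, synth.molecules, synth.proteins)
    fps = {m.ligand_id: fingerprint(m) for m in library.molecules}
    clusters = affinity_propagation(build_similarity_edges(fps))
    profiles = annotate_proteins(kept, clusters)
    lcbn_sim = jaccard_similarity_matrix(profiles)
    order = [i for i, pid in enumerate(synth.distance_ids) if pid in profiles]
    sbn_sim = sequence_similarity_matrix(
        synth.distances[np.ix_(order, order)],
        [synth.distance_ids[i] for i in order],
    )
    return EndToEnd(cfg, library, synth, kept, fps, clusters, profiles, lcbn_sim, sbn_sim)
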