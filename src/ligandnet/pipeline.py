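"""End-to-end orchestration: inputs -> clusters -> profiles -> networks ->
communities -> comparison report -> knowledge base, plus the run manifest.

The manifest records the tool version, fingerprint family and parameters,
every threshold, the seeds and the SHA-256 digests of inputs and outputs,
so a rerun with the same configuration can be checked for bit-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, defaults
from .chem import fingerprint, write_fingerprints
from .clustering import (
    affinity_propagation,
    build_similarity_edges,
    cluster_size_histogram,
    write_clusters_json,
    write_clusters_tsv,
)
from .knowledge import build_knowledge_base, save_knowledge_base
from .network import (
    Partition,
    build_network,
    communities_ap,
    connected_components,
    nmi,
    write_graphml,
    write_partition_tsv,
)
from .protein_space import (
    annotate_proteins,
    filter_interactions,
    jaccard_similarity_matrix,
    promiscuity_stats,
    read_distance_matrix,
    read_fasta,
    read_interactions_tsv,
    sequence_similarity_matrix,
    write_profiles_tsv,
)
from .synthetic import (
    SynthConfig,
    make_interaction_table,
    make_ligand_library,
    write_synthetic_inputs,
)

log = logging.getLogger(__name__)

__all__ = ["validate_config", "pipeline_run", "family_partition", "ConfigError"]


class ConfigError(ValueError):
    """A pipeline configuration value is missing or out of range."""


_THRESHOLD_RANGES = {
    "ligand_edge": (0.0, 1.0),
    "network_edge": (0.0, 1.0),
    "max_affinity_nM": (0.0, float("inf")),
    "max_mw_Da": (0.0, float("inf")),
    "min_seq_len": (0, 100_000),
}


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Fill defaults and reject out-of-range values with field-level errors."""
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed: must be an integer")
    thresholds = {
        "ligand_edge": defaults.LIGAND_EDGE_THRESHOLD,
        "network_edge": defaults.NETWORK_EDGE_THRESHOLD,
        "max_affinity_nM": defaults.MAX_AFFINITY_NM,
        "max_mw_Da": defaults.MAX_LIGAND_MW_DA,
        "min_seq_len": defaults.MIN_PROTEIN_LENGTH,
    }
    thresholds.update(cfg.get("thresholds", {}))
    for name, value in thresholds.items():
        if name not in _THRESHOLD_RANGES:
            raise ConfigError(f"thresholds.{name}: unknown field")
        lo, hi = _THRESHOLD_RANGES[name]
        if not (lo <= float(value) <= hi):
            raise ConfigError(f"thresholds.{name}: {value} outside [{lo}, {hi}]")
    cfg["thresholds"] = thresholds
    ap = {"preference": defaults.AP_PREFERENCE, "damping": defaults.AP_DAMPING}
    ap.update(cfg.get("ap", {}))
    if not 0.5 <= float(ap["damping"]) < 1.0:
        raise ConfigError(f"ap.damping: {ap['damping']} outside [0.5, 1)")
    cfg["ap"] = ap
    if "inputs" not in cfg:
        synth = cfg.get("synthetic", {})
        try:
            SynthConfig(seed=cfg["seed"], **synth)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"synthetic: {exc}") from exc
        cfg["synthetic"] = synth
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def family_partition(families: dict[str, str], nodes: list[str]) -> Partition:
    """Gene-family labels as a partition; unlabelled nodes share one class."""
    labels = sorted({families.get(n, "unassigned") for n in nodes})
    index = {f: i for i, f in enumerate(labels)}
    return Partition(
        assignment={n: index[families.get(n, "unassigned")] for n in nodes},
        method="family",
    )


def pipeline_run(config: dict[str, Any], output_dir: str | Path) -> dict[str, Any]:
    """Run the whole pipeline and return the manifest.

    With a ``synthetic`` section the inputs are generated (and written next
    to the outputs); with an ``inputs`` section they are read from disk:
    ``interactions`` (TSV), ``sequences`` (FASTA), ``distances`` (square
    matrix), optional ``families`` (TSV).
    """
    cfg = validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = cfg["thresholds"]
    manifest: dict[str, Any] = {
        "tool": "ligandnet",
        "version": __version__,
        "fingerprint": {
            "family": defaults.FP_FAMILY,
            "n_bits": defaults.FP_N_BITS,
            "depth": defaults.FP_DEPTH,
        },
        "thresholds": th,
        "ap": cfg["ap"],
        "nmi_normalizer": "arithmetic",
        "seed": cfg["seed"],
        "inputs": {},
        "outputs": {},
        "stages": {},
    }

    # ---- stage: inputs
    if "inputs" in cfg:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        records, molecules = read_interactions_tsv(paths["interactions"])
        families = {}
        if "families" in paths:
            with open(paths["families"]) as fh:
                fh.readline()
                for line in fh:
                    pid, fam = line.rstrip("\n").split("\t")
                    families[pid] = fam
        proteins = read_fasta(paths["sequences"], families)
        dist_ids, distances = read_distance_matrix(paths["distances"])
        annotations = {}
        manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
    else:
        library = make_ligand_library(SynthConfig(seed=cfg["seed"], **cfg["synthetic"]))
        synth = make_interaction_table(
            SynthConfig(seed=cfg["seed"], **cfg["synthetic"]), library
        )
        input_dir = out / "inputs"
        write_synthetic_inputs(input_dir, library, synth)
        records, molecules = synth.records, synth.molecules
        proteins = synth.proteins
        families = {p.protein_id: p.family for p in proteins.values()}
        dist_ids, distances = synth.distance_ids, synth.distances
        annotations = {
            "protein_pathways": synth.protein_pathways,
            "protein_diseases": synth.protein_diseases,
            "cluster_adverse_reactions": synth.cluster_adverse_reactions,
        }
        manifest["inputs"] = {
            p.name: _sha256(p) for p in sorted(input_dir.iterdir())
        }

    # ---- stage: filter
    kept, report = filter_interactions(
        records, molecules, proteins,
        max_affinity_nM=th["max_affinity_nM"],
        max_mw_Da=th["max_mw_Da"],
        min_seq_len=th["min_seq_len"],
    )
    manifest["stages"]["filter"] = report.as_dict()

    # ---- stage: fingerprints and ligand clustering
    used_ligands = sorted({r.ligand_id for r in kept})
    fps = {lid: fingerprint(molecules[lid]) for lid in used_ligands}
    write_fingerprints(fps, out / "fingerprints.tsv")
    edges = build_similarity_edges(fps, threshold=th["ligand_edge"])
    clusters = affinity_propagation(
        edges,
        preference=cfg["ap"]["preference"],
        mol_weights={lid: molecules[lid].mol_weight for lid in used_ligands},
        damping=cfg["ap"]["damping"],
    )
    write_clusters_tsv(clusters, out / "clusters.tsv")
    write_clusters_json(clusters, out / "clusters.json")
    manifest["stages"]["clustering"] = {
        "n_ligands": len(used_ligands),
        "n_clusters": len(clusters),
        "size_histogram": {str(k): v for k, v in sorted(cluster_size_histogram(clusters).items())},
    }

    # ---- stage: profiles and similarity matrices
    profiles = annotate_proteins(kept, clusters)
    write_profiles_tsv(profiles, out / "profiles.tsv")
    lcbn_sim = jaccard_similarity_matrix(profiles)
    order = [i for i, pid in enumerate(dist_ids) if pid in profiles]
    seq_ids = [dist_ids[i] for i in order]
    seq_sim = sequence_similarity_matrix(
        np.asarray(distances)[np.ix_(order, order)], seq_ids
    )

    # ---- stage: networks
    lcbn = build_network(lcbn_sim, threshold=th["network_edge"], kind="LCBN")
    sbn = build_network(seq_sim, threshold=th["network_edge"], kind="SBN")
    write_graphml(lcbn, out / "lcbn.graphml", families)
    write_graphml(sbn, out / "sbn.graphml", families)
    for net, name in ((lcbn, "LCBN"), (sbn, "SBN")):
        comps = connected_components(net, include_isolated=False)
        manifest["stages"][name] = {
            "n_nodes": len(net.nodes),
            "n_edges": net.edge_count(),
            "n_isolated": len(net.isolated),
            "n_components": len(comps),
            "giant_component": len(comps[0]) if comps else 0,
        }

    # ---- stage: communities and comparison
    lcbn_part = communities_ap(lcbn_sim, preference=cfg["ap"]["preference"])
    sbn_part = communities_ap(seq_sim, preference=cfg["ap"]["preference"])
    fam_part = family_partition(families, sorted(profiles))
    write_partition_tsv([lcbn_part, sbn_part, fam_part], out / "partitions.tsv")
    report_rows = [
        ("LCBN", "SBN", nmi(lcbn_part, sbn_part)),
        ("LCBN", "family", nmi(lcbn_part, fam_part)),
        ("SBN", "family", nmi(sbn_part, fam_part)),
    ]
    with open(out / "nmi_report.tsv", "w") as fh:
        fh.write("partition_a\tpartition_b\tnmi\n")
        for a, b, v in report_rows:
            fh.write(f"{a}\t{b}\t{v:.6f}\n")
    manifest["stages"]["communities"] = {
        "LCBN": lcbn_part.n_communities,
        "SBN": sbn_part.n_communities,
        "nmi": {f"{a}-{b}": round(v, 6) for a, b, v in report_rows},
    }

    # ---- stage: promiscuity tables
    stats = promiscuity_stats(kept, clusters, profiles, families)
    stats.ligand_targets.to_csv(out / "ligand_promiscuity.tsv", sep="\t", index=False)
    stats.cluster_stats.to_csv(out / "cluster_promiscuity.tsv", sep="\t", index=False)
    stats.protein_stats.to_csv(out / "protein_promiscuity.tsv", sep="\t", index=False)
    if stats.family_clusters is not None:
        stats.family_clusters.to_csv(out / "family_clusters.tsv", sep="\t", index=False)

    # ---- stage: knowledge base
    kb = build_knowledge_base(clusters, fps, kept, **annotations)
    save_knowledge_base(kb, out / "kb")

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
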