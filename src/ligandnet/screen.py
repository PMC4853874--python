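"""Ligand-set virtual screening: fusion scores, AUC and the repeated-split
benchmark.

Four scoring rules combine a query's Tanimoto similarities to a set of
known actives:

* ``MAX`` — best similarity to any training active;
* ``KNN3`` — mean of the 3 largest similarities;
* ``MPS`` — mean similarity over the whole training set;
* ``EXEMPLAR`` — best similarity over cluster exemplars only, after
  affinity-propagation clustering of the training actives.  EXEMPLAR needs
  one comparison per cluster instead of one per ligand, which is the point
  of the method.

The benchmark repeatedly samples 20 % of each target's actives as the
training set, scores the held-out actives against all decoys, summarizes
method performance as ROC AUC, and compares methods with a Friedman rank
test plus pairwise post hoc comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import defaults
from .chem import Fingerprint, Molecule, fingerprint, read_smi, tanimoto, write_smi
from .clustering import LigandCluster, affinity_propagation, build_similarity_edges
from .errors import DegenerateLabels, EmptyTrainingSet, InsufficientActives

log = logging.getLogger(__name__)

METHODS = ("MAX", "KNN3", "MPS", "EXEMPLAR")

__all__ = [
    "METHODS",
    "ScreenSet",
    "ScoreVector",
    "BenchmarkResult",
    "fusion_score",
    "exemplar_score",
    "auc",
    "run_benchmark",
    "friedman_posthoc",
    "load_screen_sets",
    "write_screen_sets",
]


@dataclass
class ScreenSet:
    """Actives and decoys for one target."""

    target_id: str
    actives: list[Molecule]
    decoys: list[Molecule]

    def __post_init__(self):
        overlap = {m.ligand_id for m in self.actives} & {m.ligand_id for m in self.decoys}
        if overlap:
            raise ValueError(f"{self.target_id}: ids in both actives and decoys: {sorted(overlap)[:5]}")


@dataclass
class ScoreVector:
    """Per-item scores of one method, with active/decoy labels."""

    method: str
    scores: dict[str, float]
    labels: dict[str, str]  # item id -> "active" | "decoy"

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ids = sorted(self.scores)
        y = np.asarray([1 if self.labels[i] == "active" else 0 for i in ids])
        s = np.asarray([self.scores[i] for i in ids])
        return y, s


@dataclass
class BenchmarkResult:
    """Repeated-split benchmark output."""

    table: pd.DataFrame            # target, repeat, method, auc
    mean_auc: dict[str, float]
    friedman_statistic: float
    friedman_p: float
    posthoc_p: pd.DataFrame        # methods x methods
    eval_reduction_pct: float      # mean % fewer similarity evaluations (EXEMPLAR vs MAX)


def _similarities(query_fp: Fingerprint, train_fps: list[Fingerprint]) -> np.ndarray:
    return np.asarray([tanimoto(query_fp, t) for t in train_fps])


def fusion_score(
    query_fp: Fingerprint,
    train_fps: list[Fingerprint],
    method: str,
    k: int = defaults.KNN_K,
) -> float:
    """Group-fusion score of a query against a training set.

    ``MAX`` is the largest similarity, ``KNN3`` the mean of the ``k``
    largest (all of them if fewer than ``k``), ``MPS`` the mean over the
    whole set.
    """
    if not train_fps:
        raise EmptyTrainingSet("no training fingerprints")
    sims = _similarities(query_fp, train_fps)
    if method == "MAX":
        return float(sims.max())
    if method == "KNN3":
        top = np.sort(sims)[::-1][: min(k, sims.size)]
        return float(top.mean())
    if method == "MPS":
        return float(sims.mean())
    raise ValueError(f"unknown fusion method {method!r} (use exemplar_score for EXEMPLAR)")


def exemplar_score(
    query_fp: Fingerprint,
    clusters: list[LigandCluster],
    fps: dict[str, Fingerprint],
) -> float:
    """Best similarity between the query and any cluster exemplar.

    Only exemplars are compared — one evaluation per cluster — so the score
    can only match or fall below the MAX fusion score over all members.
    """
    if not clusters:
        raise EmptyTrainingSet("no clusters")
    return float(max(tanimoto(query_fp, fps[c.exemplar_id]) for c in clusters))


def auc(scores: ScoreVector) -> float:
    """Rank-based AUC: P(random active outscores random decoy), ties 1/2.

    Raises
    ------
    DegenerateLabels
        Without at least one active and one decoy.
    """
    y, s = scores.arrays()
    if y.min() == y.max():
        raise DegenerateLabels("need at least one active and one decoy")
    return float(roc_auc_score(y, s))


def run_benchmark(
    sets: list[ScreenSet],
    train_fraction: float = defaults.TRAIN_FRACTION,
    repeats: int = defaults.N_REPEATS,
    seed: int = 0,
    edge_threshold: float = defaults.LIGAND_EDGE_THRESHOLD,
    preference: float = defaults.AP_PREFERENCE,
) -> BenchmarkResult:
    """Repeated-split screening benchmark over all four methods.

    Per target and repeat: ceil(``train_fraction`` * n_actives) actives are
    sampled as the training set and clustered by affinity propagation on
    the thresholded Tanimoto graph; remaining actives plus all decoys are
    scored by MAX, KNN3, MPS and EXEMPLAR; each method's AUC enters one
    (target, repeat) block of the Friedman analysis.  The per-(target,
    repeat) random streams are derived deterministically from ``seed``.

    Raises
    ------
    InsufficientActives
        If a split would leave no training or no test actives.
    """
    rows = []
    reductions = []
    for t_idx, sset in enumerate(sorted(sets, key=lambda s: s.target_id)):
        act_ids = sorted(m.ligand_id for m in sset.actives)
        n_train = math.ceil(train_fraction * len(act_ids))
        if n_train < 1 or n_train >= len(act_ids):
            raise InsufficientActives(
                f"{sset.target_id}: {len(act_ids)} actives cannot give non-empty "
                f"training and test sets at fraction {train_fraction}"
            )
        mols = {m.ligand_id: m for m in sset.actives + sset.decoys}
        fps = {lid: fingerprint(m) for lid, m in mols.items()}
        decoy_ids = sorted(m.ligand_id for m in sset.decoys)
        for rep in range(repeats):
            rng = np.random.default_rng([seed, t_idx, rep])
            train_ids = sorted(rng.choice(act_ids, size=n_train, replace=False).tolist())
            test_actives = [a for a in act_ids if a not in set(train_ids)]
            train_fps = [fps[t] for t in train_ids]
            clusters = affinity_propagation(
                build_similarity_edges({t: fps[t] for t in train_ids}, edge_threshold),
                preference=preference,
            )
            labels = {i: "active" for i in test_actives}
            labels.update({i: "decoy" for i in decoy_ids})
            vectors = {m: ScoreVector(m, {}, labels) for m in METHODS}
            for item in test_actives + decoy_ids:
                sims = _similarities(fps[item], train_fps)
                top = np.sort(sims)[::-1][: min(defaults.KNN_K, sims.size)]
                vectors["MAX"].scores[item] = float(sims.max())
                vectors["KNN3"].scores[item] = float(top.mean())
                vectors["MPS"].scores[item] = float(sims.mean())
                vectors["EXEMPLAR"].scores[item] = exemplar_score(fps[item], clusters, fps)
            for m in METHODS:
                rows.append((sset.target_id, rep, m, auc(vectors[m])))
            reductions.append(100.0 * (1 - len(clusters) / len(train_ids)))

    table = pd.DataFrame(rows, columns=["target", "repeat", "method", "auc"])
    mean_auc = table.groupby("method")["auc"].mean().to_dict()
    blocks = table.pivot_table(index=["target", "repeat"], columns="method", values="auc")
    blocks = blocks[list(METHODS)]
    statistic, p, posthoc = friedman_posthoc(blocks.to_numpy(), methods=list(METHODS))
    return BenchmarkResult(
        table=table,
        mean_auc=mean_auc,
        friedman_statistic=statistic,
        friedman_p=p,
        posthoc_p=posthoc,
        eval_reduction_pct=float(np.mean(reductions)),
    )


def friedman_posthoc(
    auc_table: np.ndarray,
    methods: list[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Friedman rank test over blocks plus pairwise post hoc comparisons.

    The global test is the classic Friedman chi-square over within-block
    midranks.  Post hoc pairwise p-values use the standard large-sample
    comparison of mean ranks: z = (R_i - R_j) / sqrt(k(k+1)/(6 n)), with a
    two-sided normal tail.  Blocks in which every method ties contribute no
    information; if all blocks are constant the statistic is 0 and every
    p-value 1 (a warning is emitted).
    """
    X = np.asarray(auc_table, dtype=float)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 methods and 2 blocks")
    methods = methods or [f"m{j}" for j in range(k)]
    ranks = np.vstack([stats.rankdata(row) for row in X])
    mean_ranks = ranks.mean(axis=0)

    if np.all(X.max(axis=1) == X.min(axis=1)):
        warnings.warn("constant ranks in every block; Friedman test is uninformative",
                      stacklevel=2)
        statistic, p = 0.0, 1.0
    elif k == 2:
        statistic = float(12.0 * n / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2) ** 2))
        p = float(stats.chi2.sf(statistic, df=k - 1))
    else:
        statistic, p = stats.friedmanchisquare(*(X[:, j] for j in range(k)))
        statistic, p = float(statistic), float(p)

    se = math.sqrt(k * (k + 1) / (6.0 * n))
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            P[i, j] = P[j, i] = float(2.0 * stats.norm.sf(abs(z)))
    return statistic, p, pd.DataFrame(P, index=methods, columns=methods)


# ---------------------------------------------------------------------------
# DUD-style directory layout: one directory per target with actives.smi and
# decoys.smi


def load_screen_sets(root: str | Path) -> list[ScreenSet]:
    sets = []
    for target_dir in sorted(Path(root).iterdir()):
        if not target_dir.is_dir():
            continue
        actives_path = target_dir / "actives.smi"
        decoys_path = target_dir / "decoys.smi"
        if not actives_path.exists() or not decoys_path.exists():
            log.warning("skipping %s: missing actives.smi/decoys.smi", target_dir)
            continue
        sets.append(
            ScreenSet(
                target_id=target_dir.name,
                actives=read_smi(actives_path),
                decoys=read_smi(decoys_path),
            )
        )
    if not sets:
        raise FileNotFoundError(f"no target directories under {root}")
    return sets


def write_screen_sets(sets: list[ScreenSet], root: str | Path) -> None:
    root = Path(root)
    for sset in sets:
        d = root / sset.target_id
        d.mkdir(parents=True, exist_ok=True)
        write_smi(sset.actives, d / "actives.smi")
        write_smi(sset.decoys, d / "decoys.smi")
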