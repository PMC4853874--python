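# Methods

## Model

The package represents proteins by the chemistry that binds them. Ligands
are clustered by 2D-structure similarity; a protein's *cluster profile* is
the binary vector whose *i*-th bit marks at least one retained interaction
with a member of ligand cluster *i*. Two proteins are chemically similar
when their profiles overlap (Jaccard index), regardless of sequence. The
central comparison of the pipeline is between this ligand-cluster view
(LCBN) and the conventional sequence view (SBN) of the same protein set,
and the central application is exemplar screening: a query molecule is
matched against one representative per cluster instead of every known
active.

Assumptions worth stating explicitly:

- *Similar structures, similar activity.* Clusters are built purely from
  2D hashed-path fingerprints; activity cliffs (small edits with large
  potency changes) are invisible at this level.
- *Binary binding.* An interaction either passes the affinity filter or
  does not; potency beyond the 10 µM cutoff does not weight the profile.
- *Cluster-level annotation.* Two proteins binding different members of
  one cluster are treated as sharing that chemotype.

## Fingerprints and similarity

Fingerprints are RDKit hashed linear-path fingerprints, 2048 bits, paths
up to 7 bonds (`maxPath=7`). Any deterministic hashed path fingerprint of
the same dimensions satisfies the pipeline's contracts; the family and
parameters are recorded in every run manifest so runs are comparable.
Tanimoto is computed by exact bit arithmetic. Conventions for degenerate
inputs: two all-zero vectors score 1.0 (identical objects), zero versus
non-zero scores 0.0. The same convention applies to profile Jaccard
(all-zero profiles cannot occur by construction — a protein enters the
profile map only through a retained interaction — and this is asserted).

## Interaction filters

A record is kept iff affinity ≤ 10 000 nM (inclusive), ligand weight
< 800 Da (exclusive), protein length > 80 residues (exclusive); affinity
types outside {Ki, Kd, EC50, IC50} and unresolvable identifiers are
dropped and counted. Each dropped record is charged to the first rule it
fails (resolution → type → affinity → weight → length), so the report's
counts sum to the input size. A ligand–protein pair with several
measurements is kept if any one measurement passes — the pipeline counts
distinct interactions, not assays.

## Affinity propagation

Clustering uses scikit-learn's `AffinityPropagation` on a precomputed
similarity matrix, wrapped by this package's engine, which fixes the
orchestration:

- **Per component.** For ligands, only pairs above the 0.5 edge threshold
  carry similarity; connected components of that graph are independent
  (no path of retained similarity can join them), so message passing runs
  per component. Within a component, pairs below the threshold are
  imputed at −10 — far below any real similarity, so they never pay to
  share an exemplar. Ligands with no edge at all become singleton
  clusters with themselves as exemplar.
- **Dense for communities.** For protein communities the matrix is dense
  and a zero Jaccard is a *real* similarity, not a missing one, so the
  engine runs once on the full matrix (the integrate-network view).
  Proteins with no positive similarity to anyone are split off as
  singletons first; this also makes the behaviour on an identity matrix
  (all singletons) well defined rather than dependent on how the solver
  breaks total ties.
- **Parameters.** Shared preference 0 on the [0, 1] similarity scale
  (below every informative similarity, so cluster counts stay small
  within components); damping 0.5–0.9 supported with default **0.7**.
  Both failure modes of the extremes were observed on planted data:
  light damping (0.5) oscillates on blocks of exactly tied similarities
  (identical profiles produce them) and shatters those blocks, while
  heavy damping (0.9) can settle on spurious fixed points that merge
  well-separated blocks. 0.7 recovered planted structure in both the
  ligand-cluster and the sequence view at every seed tried. Up to 1000
  iterations with a 50-iteration convergence window.
- **Determinism.** Items are sorted by id before clustering and the
  solver's tie-breaking perturbation is seeded with a fixed constant, so
  a given input always yields the same partition. If no exemplar
  emerges, the component falls back to singletons with a warning — a
  degraded but valid partition, never a crash.

An independently written Frey–Dueck message-passing implementation lives
in the test suite and must agree with the engine (identical exemplar sets
or identical partitions) on random dense instances.

## Networks and comparison

Threshold networks keep edges with similarity strictly above 0.25;
isolated nodes are retained in the graph object, flagged, and excluded
from giant-component statistics. NMI between partitions uses the
arithmetic-mean normalizer by default (max-normalization behind a flag);
the choice is recorded in the run manifest. Partitions over different
node universes are compared on the intersection with a warning; an NMI
against a constant labelling is 0 by convention. Gene-family labels enter
the comparison as a partition in which unlabelled proteins share one
"unassigned" class. infomap (via python-igraph) and MCL (via the `mcl`
executable, inflation 4.0) are adapters around external implementations;
a missing backend raises a typed error that callers report as a skip.

## Screening benchmark

Per target and repeat, ⌈0.2 · n_actives⌉ actives are sampled as training
set (ceiling, so at least one), clustered with the standard pipeline
settings; held-out actives and all decoys are scored by MAX, 3NN, MPS and
EXEMPLAR. MPS is implemented as the arithmetic mean of the query's
similarities to *all* training actives (top-k variants configurable) —
the mean-pairwise reading of group fusion. AUC is rank-based with
midranks for ties. The Friedman test runs over (target × repeat) blocks;
post hoc pairwise p-values use the large-sample comparison of mean ranks,
*z = (R̄ᵢ − R̄ⱼ)/√(k(k+1)/6n)*, two-sided. Blocks where all methods tie
carry no rank information; an all-constant table returns statistic 0 and
p = 1 with a warning. Random streams are derived per (target, repeat)
from the master seed, so the benchmark is reproducible and individual
cells can be recomputed in isolation.

## Synthetic data

The generator produces *real molecules*, not random bit vectors, so the
whole chemistry stack (SMILES parsing, canonicalization, fingerprints) is
exercised end to end. A fast random-fingerprint path exists in the test
suite for pure-math kernels.

- **Ligand library.** 27 hand-curated rigid scaffold templates with one
  decoration site, pairwise dissimilar (cross-core Tanimoto ≲ 0.4), each
  decorated with small substituents from a 24-element pool (within-core
  pairs ≳ 0.55). One scaffold per planted cluster. Because decorated-
  scaffold similarity is not analytically predictable, the generator
  measures the achieved within/between margins and resamples decorations
  up to a retry limit rather than guaranteeing them a priori.
- **Interaction table.** Proteins are assigned round-robin to
  communities; clusters are split into contiguous blocks, one block per
  community. Defaults: 12 clusters × 10 ligands, 48 proteins, 4
  communities — three characteristic chemotypes per community. A
  community distinguished by a single cluster would be degenerate: one
  profile-noise flip bridges two such communities at Jaccard 0.5, so a
  "characteristic subset" is only meaningful with several clusters.
  Each protein binds each member of its block's clusters with
  probability 0.7 (at least one per cluster); per-cluster bits flip with
  probability 0.02; strong affinities are log-uniform in [1 nM, 10 µM];
  an extra 10 % of off-profile records above 10 µM exercises the
  filters. Community base sequences (length 200) receive 2 % point
  mutations per protein; the distance matrix is the pairwise Hamming
  fraction, giving ≈ 0.03 within and ≈ 0.95 between communities.
- **Screen sets.** 5 targets × 3 dedicated scaffolds × 12 decorations
  (36 actives each); 60 decoys per target drawn from the *other*
  targets' scaffolds — same size range, unrelated cores, the classic
  benchmark construction.
- **Evaluation queries.** New decorations (substituents unused by the
  library) of known scaffolds, paired with the true target set of their
  planted cluster — the "new ligand of a known chemotype" situation the
  prospective protocol measures.

What passing on this data does and does not show: the synthetic world has
clean cluster margins, no activity cliffs, no assay noise beyond the
planted flip rate, and community-pure sequences. Tests against it verify
the *machinery* — recovery of structure that is present, correct
bookkeeping, determinism — not performance on real pharmacology, where
cluster boundaries are soft and the two protein views genuinely disagree.

## Numerical choices and degenerate inputs

- Ranking ties (query results) break toward the lower cluster id.
- Sequence similarity is 1 − distance, clipped to [0, 1]; matrices are
  rejected on asymmetry > 1e-9, non-zero diagonal or out-of-range
  values.
- Training splits that would leave no training or no test active raise a
  typed error rather than producing a meaningless AUC.
- Problem sizes in tests and in `scripts/acceptance.py` (50-ligand
  recovery set, 48-protein community set, 5 × 50 benchmark) were chosen
  as the smallest instances at which every planted effect is
  comfortably detectable; all scale linearly in configuration if larger
  studies are wanted.

## Known limitations

- Bit-exact reproduction of other toolkits' path fingerprints is out of
  scope; only the contract (deterministic, 2048 bits, depth 7) is fixed.
- The LCBN approach cannot place a protein that has no retained ligand —
  a structural property of ligand-based views, inherited here.
- MCL and infomap results depend on their external implementations; only
  the affinity-propagation communities are fully owned by this package.
- The conditional-search AND/OR semantics treat a pathway as the set of
  its member proteins; hierarchical pathway relationships are not
  modelled.
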