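"""Pipeline-wide default parameters.

Every stage reads its defaults from here so that a run manifest can record
one coherent parameter set.
"""

# Fingerprints: hashed linear-path fingerprint, 2048 bits, paths up to 7 bonds.
FP_N_BITS = 2048
FP_DEPTH = 7
FP_FAMILY = "rdkit-path"

# Ligand-ligand similarity graph: only pairs strictly above this Tanimoto
# enter the clustering step.
LIGAND_EDGE_THRESHOLD = 0.5

# Affinity propagation: shared preference 0; damping 0.7 (light damping
# oscillates on blocks of tied similarities, heavy damping can settle on
# spurious fixed points that merge well-separated blocks), generous
# iteration budget.
AP_PREFERENCE = 0.0
AP_DAMPING = 0.7
AP_MAX_ITER = 1000
AP_CONVERGENCE_ITER = 50
# Within a connected component, pairs below the edge threshold are imputed
# with a similarity so low they can never share an exemplar profitably.
AP_MISSING_SIMILARITY = -10.0

# Interaction filters: affinity at most 10 uM (inclusive), ligand lighter
# than 800 Da (exclusive), protein longer than 80 residues (exclusive).
MAX_AFFINITY_NM = 10_000.0
MAX_LIGAND_MW_DA = 800.0
MIN_PROTEIN_LENGTH = 80
ACCEPTED_AFFINITY_TYPES = ("Ki", "Kd", "EC50", "IC50")

# Protein network display threshold: edges require similarity above 0.25.
NETWORK_EDGE_THRESHOLD = 0.25

# Screening benchmark: 20 % of actives train, 50 repeated splits, 3-nearest
# neighbour fusion.
TRAIN_FRACTION = 0.2
N_REPEATS = 50
KNN_K = 3

# Query layer: report the 10 most similar cluster exemplars.
TOP_K = 10
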