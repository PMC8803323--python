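"""Default thresholds used across the pipeline.

Every analysis stage reads its defaults from this table so that a run
manifest can record, for each knob, whether the published default or a
user override was in effect.
"""

#: Score assigned to a present nonsilent mutation.
MUTATION_SCORE = 1

#: Score assigned to mutated IGHV status (somatic hypermutation present).
IGHV_MUTATED_SCORE = 2

#: Absolute-copy-number boundaries for scoring deletions.
#: CN < 1.0 -> high-level (score 2); 1.0 <= CN <= 1.7 -> low-level (score 1).
DEL_HIGH_CEILING = 1.0
DEL_LOW_CEILING = 1.7

#: Absolute-copy-number boundaries for scoring amplifications.
#: 2.3 <= CN <= 3.7 -> low-level (score 1); CN > 3.7 -> high-level (score 2).
AMP_LOW_FLOOR = 2.3
AMP_HIGH_FLOOR = 3.7

#: Cohort mutation frequency required for a gene to enter the clustering matrix.
MUTATION_RECURRENCE_FREQ = 0.05

#: Frequency and GISTIC q-value thresholds for a copy-number region to enter
#: the clustering matrix.
SCNA_RECURRENCE_FREQ = 0.10
SCNA_Q_CUTOFF = 0.10

#: Reporting-mode recurrent-gene catalogue rule: mutated in more than this
#: many samples AND at more than this cohort frequency.
CATALOGUE_MIN_SAMPLES = 5
CATALOGUE_MIN_FREQ = 0.03

#: K range scanned during NMF consensus clustering.
K_MIN = 2
K_MAX = 10

#: Random NMF restarts per K.
N_RESTARTS = 50

#: BH-adjusted q-value below which a lesion is called a cluster marker.
MARKER_Q_CUTOFF = 0.10

#: A lesion is clonal when its cancer cell fraction strictly exceeds this.
CLONAL_CCF_THRESHOLD = 0.90

#: Temporal-order edge support needed for dashed / solid reporting.
EDGE_SUPPORT_DASHED = 3
EDGE_SUPPORT_SOLID = 5

#: Longitudinal evolution classes by maximum per-clone CCF change between
#: consecutive timepoints: < 0.2 none (clone count unchanged), 0.2..0.5
#: inclusive modest, > 0.5 drastic.
EVOLUTION_NONE_BELOW = 0.2
EVOLUTION_DRASTIC_ABOVE = 0.5

#: Euclidean merge threshold for grouping lesion CCF trajectories into clones.
TRAJECTORY_MERGE_THRESHOLD = 0.25

#: A trajectory clone counts as present at a timepoint above this mean CCF.
CLONE_PRESENCE_CCF = 0.05

#: Gaussian kernel width (Angstrom) for the 3D mutation proximity score.
WAP_KERNEL_WIDTH = 6.0

#: Default permutation count for the proximity null distribution.
WAP_N_PERM = 1000
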