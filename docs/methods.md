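# Methods

## Lesion encoding

All lesion classes are mapped to one integer scale so that a single
nonnegative matrix can carry them jointly: nonsilent mutation present
= 1; IGHV somatically hypermutated = 2; copy-number deletions score 1
for 1.0 ≤ CN ≤ 1.7 and 2 for CN < 1.0; amplifications score 1 for
2.3 ≤ CN ≤ 3.7 and 2 for CN > 3.7. Boundaries are applied exactly as
written — closed at 1.0, 1.7, 2.3 and 3.7, strict below 1.0 and above
3.7 — and the gap (1.7, 2.3) is treated as diploid-neutral (score 0 for
both kinds). A gene hit by both a mutation and a deletion contributes
two distinct columns. IGHV status for a sample with missing data is
either rejected or imputed to 0 under an explicit, logged policy;
imputation to 0 is the pipeline default because dropping a sample from
the matrix would silently change every lesion's denominator.

Two recurrence rules coexist deliberately: lesions enter the clustering
matrix at mutation frequency ≥ 5% (SCNA regions at frequency ≥ 10% with
supplied GISTIC q ≤ 0.1 — q-values are inputs, never computed here),
while the descriptive recurrent-gene catalogue uses the stricter joint
rule "mutated in > 5 samples and > 3% frequency". `select_recurrent`
exposes both as modes.

## NMF consensus clustering

The factorization minimises generalised Kullback–Leibler divergence —
the one objective the projection literature this design follows names
explicitly — by Lee–Seung multiplicative updates (tolerance 1e-6 on the
relative objective change checked every 10 iterations, cap 2000
iterations). The update kernel is implemented in-package: a consensus
run needs 450 fits (50 restarts × K = 2..10) and a selection-stability
experiment ten times that, so per-fit overhead dominates; the kernel is
cross-checked in the test suite against scikit-learn's KL solver started
from identical factors. Initialisation draws the basis H at random and
starts the coefficients W at ones. The row-symmetric start makes every
update exactly equivariant under sample reordering, so consensus
matrices permute with their input — a property the test suite asserts
bit-exactly — while restarts still diversify through H.

Per restart, each sample is assigned to its argmax coefficient; the
consensus matrix is the co-assignment frequency over restarts. Model
selection maximises the cophenetic correlation of the average-linkage
dendrogram built on (1 − consensus), with silhouette (on the same
distances) breaking ties and smaller K breaking remaining ties. Final
labels cut the chosen-K consensus dendrogram rather than taking any
single restart's argmax: the consensus structure, not one local optimum,
is the estimator. The lowest-objective restart at the chosen K supplies
the basis and coefficients kept for projection.

Marker discovery tests, per lesion × cluster, whether presence
(score ≥ 1) is more frequent inside the cluster (one-sided Fisher,
alternative "greater" — the directional reading of "higher than in
other clusters"), with BH correction across all lesion × cluster tests
jointly and a q < 0.1 flag. Validation samples are projected by
nonnegative least squares onto the trained basis restricted to shared
lesions and assigned to the nearest discovery-cluster centroid in
coefficient space under cosine distance (cosine, because NNLS
coefficient vectors of sparse score rows differ in scale more than in
direction). The number of components used for a projection-oriented fit
is configurable (the validation setting uses K = 15). All-zero
validation samples are reported unassignable (−1), never forced into a
cluster.

## 3D mutation proximity

WAP = Σ_{i<j} w_i w_j exp(−d²_ij / 2t²) over mutated residues, with
per-residue weights equal to patient counts used raw (not log-dampened)
and t = 6 Å by default; both are configurable. Distances use one
representative coordinate per residue: the Cα atom, with a logged
heavy-atom-centroid fallback. The permutation null reassigns the
observed weight multiset to residues drawn uniformly without replacement
among resolved residues — no coverage or sequence-context weighting, a
deliberate simplification documented here — and
p = (1 + #{WAP_null ≥ WAP_obs}) / (1 + n_perm), so p is never zero.
Leave-one-out attribution removes one patient at a time (a residue
leaves the mutated set only when its count reaches zero) and recomputes
p under the same seed so that full and reduced runs share random numbers;
common random numbers keep Monte-Carlo noise out of the Δlp difference.
A removal that leaves fewer than two mutated residues yields a missing
value, not a number.

## Clonal dynamics

CCF > 0.9 (strict) is clonal. Temporal ordering uses each patient's
earliest sample only: within a sample, every (clonal, subclonal) lesion
pair adds one sample of support to the directed earlier→later edge.
Edges are reportable dashed at support ≥ 3 and solid at ≥ 5; "points of
departure" are nodes with outgoing reportable edges and none incoming.

Longitudinal lesions are grouped into clones by average-linkage
agglomerative clustering of their CCF vectors across timepoints with a
0.25 Euclidean merge threshold — a deterministic, self-contained
stand-in for full phylogenetic trajectory clustering, and labelled as
such in the run manifest. The decisive statistic is the maximum absolute
change of any clone's **mean** CCF between **consecutive** timepoints
(not endpoint-to-endpoint): > 0.5 drastic, 0.2–0.5 inclusive modest,
< 0.2 none provided the clone count (clones with mean CCF ≥ 0.05 at a
timepoint) is unchanged. A sub-0.2 change with a clone-count change is
labelled modest: the no-evolution class requires both conditions, and
clone emergence or loss is evolution even when CCFs barely move. These
interpretive choices — per-clone rather than per-lesion change,
consecutive rather than any-pair timepoints — are recorded in the
output metadata of every run.

## Expression signatures

A sample's signature is the mean of log2(TPM + 1) over the set's genes;
the +1 pseudocount handles zero TPM, duplicates in a set are
deduplicated, and set genes absent from the matrix are dropped with a
logged count (symbol loss across platforms is routine and should not be
fatal). Cluster values are arithmetic means of member samples; the
"linear transformation" for display is min–max scaling of cluster means
to [0, 1], with raw means always retained. The across-cluster test is a
one-way F test; clusters with fewer than two samples are excluded with a
warning. Deletion–expression checks compare carriers (score ≥ 1) to
non-carriers per region gene with rank-sum tests and BH correction.

## Synthetic cohort generator

The generator emulates the inputs the analyses assume, at the reference
conditions: 134 samples in 4 clusters with proportions 16/23/32/28
(normalised), 34 somatic lesions plus IGHV (35 columns), each lesion a
marker of one cluster at frequency 0.8 in-cluster and 0.05 elsewhere,
and IGHV hypermutation at probability 0.9 in cluster 1 and 0.05
elsewhere. Clonal CCFs are Beta(2, 1) rescaled into (0.9, 1] — so
ground-truth clonality coincides exactly with the 0.9 classification
boundary — and subclonal CCFs are uniform on (0.1, 0.9). Per-lesion
clonal probabilities default to 0.9 for copy-number lesions and ATM, 0.3
for the subclonal-leaning mutations (NSD2, PCLO, KMT2C) and 0.75
otherwise, giving an expected cohort clonal fraction near 0.75.
Survival is exponential per cluster (hazards 0.0010/0.0095/0.0120/0.0325
per month, i.e. 5-year survival near 100/57/49/14%) with uniform
censoring over 24–120 months of follow-up.

Longitudinal patients carry three clones (truncal at CCF 1.0 plus two
subclones) of 5 lesions each over ≥ 2 timepoints under named scenarios:
stable (constant means), drift (one clone moves 0.35), sweep (one clone
rises 0.7 while another collapses) and emergent (a new clone appears
from 0). Per-lesion CCFs add Gaussian noise (sd 0.03 default) and clip
to [0, 1]. The default 16-patient mix is 1 stable / 4 drift / 11 sweep.
Expression is lognormal on the TPM scale: log2(TPM + 1) = base + cluster
shift + Gaussian noise, floored at zero TPM; default signature sets
shift ±1 log2 unit in their designated clusters over a 200-gene
background.

Reproducibility: one global integer seed expands into per-stage child
streams via `numpy.random.SeedSequence(seed).spawn` (PCG64), so cohort,
trajectories and expression are independently and bit-identically
reproducible.

What the generator does **not** emulate: realistic genome coordinates or
lesion co-occurrence structure beyond cluster membership, allele counts
or purity/ploidy uncertainty in CCFs (real CCF estimates carry
measurement error the clonal/subclonal boundary test never sees),
overlapping or nested clones violating the independent-trajectory
assumption, and marker frequencies calibrated to any real cohort.
Passing tests therefore demonstrate that the methods recover structure
they are designed for when it is present at the stated strengths — not
that real cohorts contain that structure.

## Problem sizes and numerical choices

Default consensus scans run 50 restarts per K over K = 2..10 on the
134 × 35 matrix; stability experiments repeat this over 10 cohort
seeds. Permutation p-values use 1000 draws by default (4000 where Δlp
signs are asserted); evolution-recovery checks use 200 replicate
3-patient draws at noise sd 0.03. Ties in model selection round metrics
to 12 decimals before comparison to keep floating-point noise out of the
K choice. Degenerate inputs have defined behaviour rather than crashes:
constant consensus distances return cophenetic 1 with a warning,
fully-mutated structures return p = 1 with a warning, single-lesion
trajectory tables yield singleton clones.

## Known limitations

- The trajectory clone-grouping is distance-based, not phylogenetic: it
  cannot represent nested clones or infer ancestry, only co-moving CCF
  groups.
- The permutation null for spatial clustering ignores mutational
  coverage and sequence context; structures with strongly non-uniform
  mutability will overstate significance.
- Consensus clustering on very sparse score matrices (few lesions per
  sample) can select small K spuriously; the cophenetic/silhouette pair
  is a heuristic, not an inferential test.
- Survival associations here are descriptive (KM/log-rank); no
  multivariate adjustment is implemented.
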