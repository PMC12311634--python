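# Methods

`tcrqa` assesses the quality of candidate structural models of TCR-pMHC
class I complexes and combines learned and model-confidence scores into a
consensus used for ranking docking poses and for discriminating binding
from swapped (mismatched) TCR-pMHC pairs. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Docking quality: restricted-interface DockQ

A candidate is scored against its reference with DockQ,

    DockQ = ( fnat + 1/(1 + (iRMS/1.5)^2) + 1/(1 + (LRMS/8.5)^2) ) / 3,

restricted to TCR-peptide interactions: the TCRα and TCRβ variable domains
form one merged ligand group and the peptide is the only contact partner.
MHC atoms enter neither the fnat contact definition (heavy-atom pairs
< 5 Å at residue level) nor the interface-residue set for iRMS (10 Å
criterion, backbone RMSD after interface superposition). For LRMS the
ligand (TCR) backbone RMSD is measured after superposition on the receptor
frame, which is the full pMHC by default; `receptor_frame="pep"` restricts
the frame to the peptide for sensitivity analysis. This keeps standard
DockQ receptor/ligand mechanics while honoring the interface restriction;
the grouping is configurable. CAPRI categories follow the DockQ thresholds
0.23 / 0.49 / 0.80. Hydrogens are ignored and alternate locations resolve
to the highest-occupancy conformer. Superpositions use a proper-rotation
Kabsch fit (SVD with determinant correction).

Clash counting (used by the dataset filter) counts TCR-peptide backbone
atom pairs strictly closer than 3 Å, with backbone = {N, CA, C, O} (a
missing O is simply absent from the enumeration); atom-pair counting was
chosen over residue-level minima because the filter threshold ("more than
5 clashes") reads most naturally as a pair count. TRA-peptide and
TRB-peptide tallies are kept separate and a model is removed when either
exceeds 5.

## Featurization

Each residue is a node; edges connect a node to its k = 30 nearest
C-alpha neighbors (ties broken toward the lower residue index, self-edges
excluded; distances are rounded to 1e-6 Å before sorting so the neighbor
set is stable under rigid motion of the coordinates).

Node scalars (30-dim): sin/cos of φ, ψ, ω (zeroed where undefined at chain
termini — dihedrals never cross chain boundaries), a 20-dim amino-acid
one-hot and a 4-dim chain one-hot (TCRα, TCRβ, peptide, MHC). Node vectors
(3 × 3): unit vectors toward the previous and next C-alpha in the chain
(zero vectors at termini) and the imputed C-beta direction

    normalize( (1/3)·(n×c)/||n×c|| − (2/3)·(n+c)/||n+c|| ),  n = N−CA, c = C−CA,

which is defined for every residue including glycine. Edge scalars
(32-dim): 16 Gaussian RBFs of the C-alpha distance with centers evenly
spaced on [0, 20] Å and σ equal to the spacing (the Euclidean distance is
used as the RBF argument, consistent with the architecture this follows),
plus a 16-dim sinusoidal embedding of the signed sequence offset j − i
with geometrically spaced frequencies. Inter-chain edges carry an all-zero
positional embedding because primary-sequence distance is undefined across
chains. The edge vector is the unit C-alpha direction j → i.

Optional per-residue structural embeddings (512 × N_AA, e.g. from an
inverse-folding encoder) are consumed precomputed from an HDF5 container
and concatenated after the base scalar features.

All scalar features are SE(3)-invariant and all vector features
SO(3)-equivariant / translation-invariant; the test suite verifies this
under random rigid transforms.

## The GVP-GNN regressor

The regressor is a geometric vector perceptron graph network: each GVP
mixes vector channels with rotation-equivariant channel-wise linear maps,
feeds vector norms into the scalar track, and gates output vectors with a
sigmoid computed from the scalars (vector-gating variant). Node and edge
features are first embedded to hidden dimensions (scalar 50 / vector 8 on
both), then three message-passing layers run: messages are a single GVP
over (receiver, sender, edge) features, mean-aggregated over incoming
edges, added residually, followed by a position-wise GVP feed-forward;
scalar tracks are layer-normalized after each residual. The readout
(unspecified upstream, implementation-defined here) mean-pools final node
scalars and applies two fully connected layers with dropout and a sigmoid,
so predictions live in [0, 1] like DockQ. Predictions are clamped to
[1e-4, 1] before entering any harmonic mean.

Training minimizes the pair MSE

    L = MSE(y1, p1) + MSE(y2, p2) + MSE(y1 − y2, p1 − p2)

over candidate pairs sampled uniformly within the same target (one pair
per draw, targets weighted by pool size); the difference term penalizes
fitting to features constant within a target, such as sequence. Defaults
follow the published recipe exactly: Adam, initial learning rate 1e-4,
cosine annealing to zero, weight decay 1e-4, batch size 32, 100 epochs,
dropout 0.5 on the fully connected layers only, 3 conv layers, hidden
dims 50/8/50/8. No early stopping. Two 5-fold cross-validated ensembles
are trained — one on the full DockQ range, one only on poses with
DockQ ≥ 0.5 — giving 10 networks.

The network and its training run on a compact reverse-mode automatic
differentiation engine written on NumPy (`tcrqa.nn`): dense linears, one
big GEMM for the channel-wise vector maps, sparse-matrix scatter-adds for
message aggregation, single precision throughout. Seeded initialization
and pair sampling make training reproducible bit-for-bit.

## Consensus scoring

With per-fold predictions p_1..p_5 (full range) and q_1..q_5 (≥ 0.5
subset):

    GNN_full = mean(p),   GNN_high = mean(q)
    GNN-ens  = harmonic_mean(GNN_full, GNN_high)
    GNN-AF   = harmonic_mean(GNN_full, GNN_high, AF_confidence, CDRpep_pLDDT)

CDRpep_pLDDT is the arithmetic mean of per-residue pLDDT over CDR1/2/3
residues of both TCR chains plus all peptide residues, divided by 100 so
every harmonic-mean component shares the [0, 1] scale (the rescaling is a
package choice; the formula mixes the quantities directly, which requires
a common scale). AF confidence is consumed as given. Components are
clamped to ≥ 1e-4 rather than dropped when zero. The harmonic mean weights
small components heavily — one pessimistic sub-score pulls the consensus
down, which is the desired behavior when any single score is over-confident.

CDR annotation comes either from explicit residue ranges (sidecar table)
or from a built-in approximate annotator that brackets CDR3 between the
conserved cysteine and the FGxG motif; the annotator is a crude stand-in
for a proper numbering scheme and is intended for pre-trimmed variable
domains and synthetic fixtures.

## Dataset construction

* Hobohm-1 redundancy reduction at 95% similarity: greedy single pass in
  the caller's priority order (release-date ascending when available); an
  entry is dropped when its TCRα **or** TCRβ is ≥ 95% similar to any
  retained entry. Similarity = identities / alignment length from a global
  alignment with match 1, mismatch 0, gap −1.
* Partitioning: complete-linkage agglomerative clustering (scikit-learn)
  on distance 1 − mean(simα, simβ), cut at 5 clusters. Hobohm uses
  either-chain dropping while clustering uses the average similarity; the
  two conventions are intentionally different, as each matches its own
  procedure's description.
* DockQ-bin subsampling: per target, 20 equal-width bins on [0, 1]
  (left-closed, 1.0 in the top bin), up to 20 models per bin, uniform
  without replacement, seeded.
* Clash filter: as above, threshold 5, boundary inclusive.
* Specificity tables: binders downsampled to ≤ 200 per peptide; swapped
  negatives pair each positive's pMHC with 5 donor TCRs drawn without
  replacement from positives of other peptides, never the recipient's own
  TCR; an optional constraint requires the donor's source peptide to be at
  least 3 Levenshtein edits from the recipient peptide (edit distances via
  edlib). Train/benchmark splits by release date against 2021-09-30 are a
  metadata predicate, as is the 3.5 Å resolution filter.

## Perturbation operators

MSA operators (A3M conventions, query row never touched): per-residue
random substitution at a given rate; column-wise mutation writing one
consistent random residue into every non-gap homolog entry of a selected
column (chosen so it is genuinely distinct from the per-residue operator);
row masking removing ⌊fraction·n⌋ homolog rows (with a flag to replace by
'X' tokens instead — removal is the default since masking emulates MSA
subsampling). Template perturbation adds i.i.d. Gaussian offsets to every
atomic coordinate. The four candidate-generation presets (30/30/30/60
candidates per AF model across five models, 750 total) are recorded as
data in `tcrqa.perturb.PIPELINE_PRESETS`.

## Evaluation statistics

Batch experiment: batches of 1 binder + 5 swapped negatives sharing a
pMHC; TPR = (batch_length − 1 − binder_index)/(batch_length − 1), where
binder_index is the binder's rank by descending score (score ties count
against the binder, so constant scorers get no credit); batch accuracy is
the fraction of batches with the binder first. Cumulative TPR curves sort
batches by descending maximal intra-batch score (or by TPR) and report
prefix means. Ranking reports give the global Spearman correlation between
predicted score and DockQ, the same restricted to DockQ > 0.5, the mean
per-target Spearman (targets with < 3 candidates are excluded with a
warning), and the mean DockQ of each target's top-scoring candidate.
Failed-proportion curves bin min-max-normalized scores into 10 bins and
report the fraction with DockQ < 0.23 per bin and cumulatively by rank.
Partial ROC AUC up to FPR 0.1 is trapezoid-integrated and
McClish-standardized so a random scorer gives 0.5 (a raw-area option
exists); ties are handled by grouped threshold sweeps, and the
implementation is cross-checked against scikit-learn and a brute-force
oracle.

## Synthetic data

The generator builds idealized backbones (N, CA, C, O, CB) from internal
coordinates (NeRF construction; helix φ/ψ = −57/−47, strand −139/135) and
assembles a class-I-like layout: an MHC helix platform, an extended
peptide lying on it, and two small TCR variable-domain stand-ins whose
extended CDR3 loops contact the peptide from above. Chain placement picks,
deterministically per seed, the loop spin and descent depth that maximize
residue contacts under a 3.3 Å clash floor; every native is guaranteed
≥ 5 reference contacts per TCR chain at the 5 Å criterion and zero
backbone clashes. Default chain lengths are 110/110/9/180 (TCRα/β,
peptide, MHC); the test suite uses 16/16/8/20 complexes, which exercise
identical code paths since every in-scope computation uses backbone atoms
plus the imputed C-beta only.

Decoys apply a rigid rotation + translation to the TCR dimer and Gaussian
jitter to CDR loop atoms; the default recipe ladder (geometric translation
grid from 0 to 30 Å with randomized rotation and jitter) produces true
DockQ distributions covering essentially the full [0, 1] range. Synthetic
per-model confidence is a noisy affine function of true DockQ clipped to
(0, 1) (slope 0.85, intercept 0.10, SD 0.05); a miscalibration mode gives
15% of incorrect decoys (DockQ < 0.23) confidence drawn from U(0.7, 0.9),
emulating the over-confident tail of model-internal quality estimates.
Per-residue synthetic pLDDT is 100·clip(0.80·DockQ + 0.15 + ε) with ε
noisier (SD 0.10 vs 0.04) on interface (CDR + peptide) residues.

What the generator does **not** emulate: side-chain packing, sequence-
structure consistency, realistic energetics, or the failure modes of real
structure predictors beyond the monotone-confidence + over-confident-tail
model. Tests passing on these fixtures therefore demonstrate correctness
of the machinery (metrics, featurization, training dynamics, consensus
algebra, dataset procedures) and the learnability of geometric quality
signal — not performance on real TCR-pMHC models.

## Parameter-recovery experiment

The end-to-end check trains the two 5-fold ensembles on 5 synthetic
targets × 24 graded decoys (16/16/8/20 chains, k = 10 graphs), 18 epochs,
learning rate 3e-3, batch size 8, dropout 0. Dropout is disabled in this
experiment only: with ~120 training poses and a few hundred optimizer
steps, 0.5 dropout on the pooled readout keeps the network at the
target-mean prediction; the pair-difference loss and the small capacity
regularize instead. Out-of-fold predictions pooled across folds reach
Spearman ≈ 0.85 against true DockQ (three independent seeds), and the
GNN-AF consensus built from both ensemble halves plus synthetic
confidence/pLDDT ranks fresh binder batches (binder = low-distortion
decoy, negatives = high-distortion) with cumulative TPR 1.0 over the
top-score decile. Problem sizes were chosen so the full suite trains on
one CPU in minutes.

## Numerical choices and degenerate inputs

* Nearest-neighbor distance rounding at 1e-6 Å (edge-set stability).
* Orientation vectors at chain termini are zero vectors rather than
  dropped, keeping tensor shapes fixed; the accompanying sin/cos features
  are zeroed with a defined-ness flag.
* Degenerate C-beta imputation (parallel or zero n/c) raises.
* Harmonic-mean inputs clamped at 1e-4; network outputs likewise.
* kNN on complexes with N ≤ k residues falls back to N − 1 neighbors.
* The smooth vector norm inside GVPs uses sqrt(Σx² + 1e-8).
* Single precision in the network backend; float64 everywhere else.

## Known limitations

* The built-in CDR annotator is approximate; real pipelines should supply
  explicit ranges from their numbering tool.
* The DockQ implementation supports exactly the four TCR-pMHC chain roles,
  not arbitrary multimers.
* Resolution and release-date filters operate on metadata columns; they
  cannot be recomputed from coordinates.
* Training at published scale (hundreds of epochs, tens of thousands of
  graphs) is possible but slow on the NumPy backend; the package targets
  method correctness and small-to-medium experiments.
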