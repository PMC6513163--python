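# Methods

## Region boundary construction

Each protein is partitioned into continuous candidate functional regions
from its typed feature annotations. Repeat and Site annotations never
shape boundaries (they are re-attached as features afterwards). Signal
peptides are claimed first and always kept as regions. The remaining
tiers claim residues in strict precedence order — Domain; Family together
with Homologous superfamily; unintegrated signatures; transmembrane;
non-transmembrane; disorder — where each tier union-merges its
*overlapping* intervals (adjacent-but-touching intervals stay separate
regions), clips the result to residues no higher tier has claimed, and
drops fragments shorter than one residue. Residues claimed by nothing
become Unassigned regions.

Two length rules then clean up the partition, both with strict
inequalities so boundary values (exactly 18 or 20 residues) survive:

* **Terminal rule** — an Unassigned region at either protein terminus
  shorter than 18 residues is merged into its neighbouring region; this
  floor is tuned to signal/targeting peptide lengths so real terminal
  signals are not fused away.
* **Linker rule** — an interior Unassigned region shorter than 20
  residues is discarded outright (typical inter-domain linkers), leaving
  a residue gap that belongs to no region. Coverage bookkeeping treats
  these residues as unrepresented.

When the only neighbour of a short terminal Unassigned region is a
signal-peptide region and the protein has other regions, the terminal
region is kept separate rather than merged: merging would either corrupt
the signal peptide or require a non-contiguous region, and signal
peptides are more useful intact. A protein with no usable annotations is
one Unassigned region regardless of length. Feature annotations
(including Repeats and Sites) attach to the single region that maximizes
overlap, provided the overlap covers at least 75% of the annotation;
annotations failing that test are multi-region spanners and contribute
only to whole-protein vectors.

Coordinates are 1-based inclusive internally (UniProt/InterPro
convention) and converted to 0-based half-open only in the BED-like TSV
serialization. The InterProScan 5 TSV has no explicit entry-type column,
so types resolve in this order: a user-supplied map from signature or
InterPro IDs to types (mirroring InterPro's `entry.list`), then
per-analysis rules (Phobius signal/transmembrane/non-cytoplasmic,
MobiDB-lite disorder, Gene3D and SUPERFAMILY as homologous
superfamilies), then `UnintegratedSignature` for rows with no InterPro
entry, else `Other`.

## Feature spaces and the kernel

Regions (and whole proteins, for the baseline) are encoded in four
spaces: overlapping k-mers of the region sequence (k = 3 by default, a
compromise between fold information and dimensionality; configurable),
keywords tokenized from feature descriptions (split on any
non-alphanumeric character, case-folded by default, no stop-word list),
InterPro entry IDs, and member-database signature IDs including
unintegrated entries. Counts are TF-IDF weighted with the smoothed
variant idf(f) = ln((1+N)/(1+df(f))) + 1 and L2 row normalization, so
cosine similarity lies in [0, 1]; the vocabulary is frozen at fit time
and unseen features are dropped on transform. Whole-protein k-mers are
computed on the full sequence so junction k-mers spanning region borders
are included; in the other spaces the protein vector is the sum of its
region counts plus the multi-region spanners.

The similarity kernel κ is the cosine matrix with everything below the
95th percentile of off-diagonal similarities zeroed; the percentile is
estimated from all pairwise similarities among up to 10,000 regions
sampled without replacement under a seed, with zero similarities included
in the percentile population (excluding them would inflate the cutoff
badly in sparse spaces). The diagonal stays at 1 for nonzero rows.

## The group-instance cost function

Per GO term, θ minimizes

J(θ) = 1/N_p Σ_k Δ(Ŷ_k, Y_k) + w₁/N_r² Σ_ij κ(x_i,x_j) Δ(ŷ_i,ŷ_j)
     + w₂/N_r⁺ Σ_{i∈r⁺} Δ(ŷ_i, y_i) + λ/N_p ‖θ‖²,

with Δ the square loss and ŷ the logistic score. Numerical choices:

* **Max subgradient** — the protein-fit term differentiates through the
  arg-max region only, ties broken to the lowest region index
  (deterministic).
* **Intercept** — a constant-1 feature is appended to every vector; its
  weight is excluded from the ridge penalty so calibration is not
  shrunk.
* **Empty anchors** — when N_r⁺ = 0 the third term is identically zero.
* **Kernel diagonal** — contributes exactly zero (Δ(ŷ_i, ŷ_i) = 0), so
  including or excluding it cannot change J; a test asserts this.
* **Stability** — sigmoid evaluated in its log-sum-exp-stable form;
  smoothness-term accumulation in extended precision.

Training is minibatch SGD with momentum. A batch is a set of whole
proteins with all their regions; every normalizer (N_p, N_r², N_r⁺) is
replaced by its in-batch counterpart so term magnitudes stay comparable
across batch sizes, and the smoothness term either uses all in-batch
pairs (the default, which keeps small runs exactly testable) or a
uniform sample of ordered pairs (`pair_sample`). Defaults, all
overridable and logged in the model archive: w₁ = w₂ = λ = 1, learning
rate 0.1 with 1/√epoch decay, momentum 0.9, 32 proteins per batch, at
most 200 epochs, early stopping after 10 epochs without improvement of
validation protein-level AUPR (training AUPR when no validation split is
given; cost when validation has a single class). The returned θ is the
best-validation iterate. The seed θ comes from an L2-regularized
logistic regression on whole-protein vectors with the ridge weight
chosen from {0.1, 1, 10, 100} by validation AUPR; that same θ is the
whole-protein baseline, applied directly to region vectors for
region-level comparison since the vector spaces share one vocabulary.

## Label assembly

GAF files at two release dates give a temporal holdout: proteins
annotated to a term in the older release train, proteins that gained the
term by the newer release evaluate. Only experimental/curated evidence
codes (EXP, IDA, IMP, IGI, IEP, TAS, IC, IPI) count. NOT-qualified rows
are excluded from positives and from the negative pool (ambiguous
either way). Negatives for a term are proteins with at least one
qualifying annotation to some other term and none to the target — nor,
behind a flag with a child→parent edge table, to any of its descendants;
no ancestor propagation of annotations is applied by default (off by a
flag, since the right choice depends on the ontology snapshot in use).
external2go-style mappings attach known positive labels to regions whose
assigned signatures match, and those labels propagate up to the parent
proteins; the matched regions form the r⁺ anchor set.

## Evaluation protocol

Region-level ground truth comes from residue-ligand contact records: a
region is binding-positive when strictly more than 3 of its residues lie
within 6 Å of the ligand (applied uniformly to all ligand classes,
configurable), and regions with under 80% structural coverage are
excluded entirely. AUPR is step-wise average precision with whole tie
groups (no trapezoidal interpolation, which overestimates PR area).
Bootstrap comparisons use 1000 resamples whose index matrix is derived
from the seed and labels alone, so any two methods on the same items
pair exactly; single-class resamples are redrawn. Differences are tested
with a two-tailed Wilcoxon signed-rank test (zeros dropped, midranks,
exact null for small tie-free samples, normal approximation with tie
correction otherwise), and positive median-AUPR deltas mean the
region-specific model wins. Positive regions are called at the threshold
maximizing F1, ties to the smaller threshold. The sequence-identity
baseline is the maximum global-alignment identity (match 1, mismatch 0,
gap −1; identities over alignment columns) to any positive template; a
BLAST outfmt-6 importer exists for parity runs against an external
aligner.

## The synthetic corpus

The generator emulates the statistical shape of a curated proteome slice
without pretending to be one: 1–6 regions per protein (1 + Poisson(2)
truncated at 6, giving ≈2.95 regions per protein on average), region
lengths uniform in [25, 400] so no generated region trips the 18/20
rules, and a Zipf-distributed background vocabulary (exponent 1.1, 500
tokens, 5 tokens per region) so TF-IDF has realistic dynamic range.
Proteins belong to 20 families; a family token appears in **every**
region of its members, and positives (30% of proteins) are sampled with
4:1 enrichment in half the families. This family vocabulary is the
essential confounder: it is label-correlated at the protein level but
not region-specific, exactly the situation in which a whole-protein
model smears functional weight across all regions of a protein while a
region-trained model can localize it (mixed families whose members share
features but not functions). Every positive protein carries the causal
feature token in exactly one region; the true region label is the causal
indicator; training labels flip each region label independently with
probability 0.05 by default and the protein label is the OR of the noisy
region labels. Contact records place four sub-6-Å residues in each
causal region with full structural coverage everywhere, so the
structure-derived evaluation labels recover the planted truth while the
training labels carry the noise — mirroring the real split between noisy
curated annotations and structure-verified binding sites.

What passing on this corpus does **not** show: the generator draws
sequences uniformly over amino acids (no homology, no composition bias),
places exactly one causal region per positive protein (no multi-region
functions), uses a single flat vocabulary rather than the four
heterogeneous spaces of real data, and has no GO-DAG structure. Results
on it demonstrate that the estimator recovers a recoverable
region-specific signal under protein-level supervision and noise, not
that any particular real GO term is this recoverable.

## Problem sizes and defaults used in shipped checks

The shipped tests and the reproduction script use 200-protein corpora
(≈590 regions), ten seeds for the recovery experiment, 1000 bootstrap
rounds, a 2000-row random matrix for the kernel-retention check, and
exhaustive enumeration up to 8 items for the average-precision check —
sizes chosen so the full battery re-runs in a few minutes on one core
while keeping every comparison statistically meaningful at its stated
tolerance.

## Known limitations

Hyperparameters (w₁, w₂, λ, optimizer settings) default to round values
and a validation grid rather than published constants; they are recorded
in every model archive. Boundary building supports one flat partition
per protein, not nested hierarchies of regions. The temporal-holdout
assembly assumes accession-stable protein identifiers between releases.
The >3-contact-residue rule is applied to single-atom metal ligands the
same as to nucleic acids (flag-configurable), which plausibly
under-labels metal sites. Exact negative-set construction for training
is a convention (annotated-elsewhere, CAFA-style), not a ground truth.
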