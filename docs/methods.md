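# Methods

This note documents the models, procedures and numerical choices behind
`crisprmca`, and what the synthetic conditions used in the test suite do
and do not establish about real data.

## Problem setting

A CRISPR-Cas9 off-target dataset is a list of aligned guide-RNA /
target-DNA pairs with a binary activity label (1 = experimentally
validated cleavage at the off-target locus).  Mismatches-only data are
23-mers (20-nt protospacer + NGG PAM); data with bulges are 24-mers in
which `_` marks the unpaired side of an insertion or deletion.  Such
datasets are extremely label-imbalanced: validated sites number in the
tens to thousands against 10^4–10^5 candidate loci.

## Imbalance diagnostics

Three scalar summaries are computed per dataset from the class counts
(p, q are the positive/negative proportions):

* **IR** = n_neg / n_pos — the headline imbalance ratio.
* **CVIR** = population σ/μ of {p, q}.  With p + q = 1 this reduces
  algebraically to |q − p|; the implementation computes the literal σ/μ
  form and the test suite asserts the identity.  This class-proportion
  reading is the one interpretation that reproduces the published values
  for all nine benchmark datasets to 4 decimals.
* **IE** = −p·log2 p − q·log2 q (bits), with 0·log 0 := 0; equal to 1 at
  perfect balance and decreasing in |p − q|.

Severity bands follow the IR: mild < 200, moderate 200–1000, severe
≥ 1000.  An additional "balanced" band (IR < 40) is used when summarizing
rebalanced datasets; its boundary is a heuristic because published
labelings near the balanced/mild border are not monotone in IR, and it is
deliberately not used anywhere as a decision rule.

## Pair encoding

The default 24×7 scheme assigns each aligned position five *base
channels* and two *direction channels*.  Base symbols carry one-hot codes
over the channel order (A, G, C, T, `_`); a position's base channels are
the bitwise OR of the guide and target codes, so matches keep one set bit
and mismatches/bulges two.  OR is used rather than XOR: XOR of two
identical one-hots is the zero vector, which cannot represent a match,
while OR reproduces the intended worked examples.  Because OR is
symmetric, two direction channels encode the orientation: [0,0] for a
match, [1,0] when the guide symbol's channel index precedes the
target's, [0,1] otherwise.  The rule is generalized from the A-T → [1,0]
and `_`-G → [0,1] examples and is isolated in one function so an
alternative convention can be swapped in.

23-mer pairs are padded to 24 rows by **prepending** one all-zero row,
keeping the PAM at the high-index end so PAM-proximal positions have the
same indices in mismatch-only and bulge-aligned inputs.  Whether padding
at the PAM-distal or PAM-proximal end is "correct" is an open
convention; the choice is recorded in the encoding metadata.

A minimal 23×4 scheme (OR of 4-bit one-hots, gap-free, no direction
channels) is also provided; the scheme enum is extensible.

## Efficiency score table

Guide-vs-target efficiency is scored as

    S = clip(a · Σ_{i=1..20} v[i, g_i, t_i] + b, 0, 1),

a per-position, per-base-pair lookup with an affine map to [0, 1].
Feature-fingerprint scoring functions of this family reduce to such a
table once their per-base-pair molecular features are aggregated, so the
table is treated as pluggable input: a CSV format
(`position,guide_base,target_base,score` plus `# a:`/`# b:` header
comments) accepts externally published values.  When a, b are not given
they are fitted from the table's attainable range (a = 1/(S_max − S_min),
b = −S_min·a, per-position extrema); a constant table maps to 0.5.

The shipped synthetic table is seeded and structured: matches contribute
≈ 1; a mismatch contributes a per-position tolerance (high at PAM-distal
positions 1–3 and 8–9, low at 10–20) times a base-pair affinity in which
wobble-like substitutions (G·A, T·C, G·T, A·C) are elevated, plus
N(0, 0.03) noise so single-substitution screens have reproducible,
non-trivial ordering.

## ESB rebalancing

For each positive training record, all 60 single-base variants of its
20-nt guide are generated and passed through two screens:

1. **Efficiency**: keep variants scoring strictly above the parent guide
   against the parent record's target protospacer.  Ties are rejected
   ("strictly better" is taken literally).
2. **Specificity**: candidate sites for each surviving variant are found
   genome-wide (NGG PAM, both strands, mismatch tolerance 1 by default)
   and specificity is the MIT-style aggregate S_on / (S_on + Σ S_off).
   The on-target of a guide is defined as its own perfect-match
   protospacer; candidate windows whose protospacer equals it are
   excluded from the off-target sum, and a guide with no remaining
   candidates is perfectly specific (1.0).  Variants strictly more
   specific than the parent pass.  The aggregate form is a design choice
   (no canonical formula exists for this screen) and is isolated in one
   function.

Accepted variants become new positive records pairing the mutated guide
(parent PAM retained) with the parent record's original target DNA.
Originals are never modified; rebalancing runs on the training split
only; variants whose guide equals any test-split guide are dropped; and
exact (guide, target) duplicates are removed from both splits at the
end.  An audit table records per-parent counts at every stage.  Bulge
(`_`) records are rejected — the screens are undefined for gapped
alignments, and the strategy is scoped to mismatches-only data.

The genome scanner enumerates all 23-mer windows on both strands whose
trailing 3-mer is NGG and whose leading 20-mer is within `max_mm`
mismatches of the guide, with 0-based half-open forward-strand
coordinates.  Ambiguous characters (N, ...) never match: they count as
protospacer mismatches, fail the GG requirement, and are not accepted in
the N slot.  The scanner is verified against an exhaustive window-scan
oracle on over a hundred seeded toy genomes; a reader for files produced
by the Cas-Offinder tool provides an interchangeable external backend for
genome-scale searches.

## The CRISPR-MCA classifier

Input is the 24×7 encoded pair.  The pipeline is: four-branch multi-scale
convolution (1×1; 1×1→3; 1×1→5; max-pool-3→1×1, ReLU after every
convolution, same-padding, channels concatenated) → layer normalization
over channels → additive sinusoidal positional encoding
(PE(pos, 2i) = sin(pos/10000^{2i/d}), cosine on odd columns) → 8-head
scaled-dot-product self-attention → additive skip connection (the
position-encoded features plus the attention output) → flatten → dense
256 → dense 128 (ReLU + dropout 0.5 after each) → dense 2 with softmax.

Interpretation choices where the design was open:

* "reshape and normalize" after the convolution block is realized as
  layer normalization over channels;
* the skip connection is additive (not concatenative);
* ablation M1 (no multi-scale block) substitutes a single 1×1 projection
  to the attention width so downstream shapes are unchanged; M2 removes
  the attention stage (the skip path remains); M3 removes the positional
  encoding.  M1 and M2 strictly reduce the parameter count; M3 is
  parameter-neutral because the sinusoidal encoding has no weights.

The network, its backward passes and the Adam optimizer (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8) are implemented directly on NumPy arrays; gradients
are verified against central finite differences in the test suite at a
generic parameter point (zero-initialized biases put entire ReLU channels
exactly at the kink, where one-sided finite differences legitimately
disagree with the subgradient convention).  Weights use Glorot-uniform
initialization, biases zero.  All randomness — initialization, epoch
shuffling, dropout — derives from the configured seed, so runs are
bit-reproducible.  Default compute precision is float32; float64 is
available for gradient verification.

Training defaults: epoch cap 500, early stopping with patience 10 on
validation loss (training loss when no validation set is supplied; the
monitored quantity is configurable), strict-improvement rule,
best-weight restoration, learning rate 1e-3, batch size 128.
Unpublished architecture widths (per-branch filters, hence the attention
width d_model = 4 × filters) default to 32/128 and are configuration
fields.  The classification threshold for recall is 0.5 on the
positive-class probability.

## Evaluation protocol

Stratified 5-fold cross-validation (stratification keeps rare positives
in every fold; grouping folds by guide is available as an option).
Within each fold, 10% of the held-out records form a tuning subset used
to monitor early stopping; metrics — recall at 0.5, ROC-AUC (trapezoid),
PR-AUC — are reported on the remaining 90% as mean ± sd over folds.
PR-AUC is the non-interpolated step integral Σ (R_n − R_{n−1}) P_n over
the precision–recall curve (computed via scikit-learn's average
precision, and checked in the tests against an independent brute-force
threshold sweep).  Single-class label vectors make the ranking metrics
undefined and raise an explicit error rather than returning 0.  When ESB
runs inside cross-validation it is applied to the training folds only;
the held-out fold is passed to the augmenter solely so the guide-leakage
rule can be enforced, which the tests verify through the audit trail.

## Synthetic data

The generator emulates the three statistical signatures of genome-wide
off-target screens that matter to this toolkit: extreme imbalance
(configurable IR), PAM-distal-skewed mismatch positions (default weights
3.0 at positions 1–3 and 8–9, 1.2 at 4–7, 0.4 at 10–20), and non-uniform
mismatch types (wobble-like substitutions over-weighted).  Targets are
unique per guide (candidate lists are unique loci; uniqueness is enforced
by rejection sampling), carry 0–4 substitutions with a count distribution
skewed toward higher counts (as in real candidate enumerations), and PAM
positions are copied so mismatches occur only over the protospacer.
Labels are assigned by thresholding a latent score — the same score-table
machinery used by the ESB screens plus N(0, 0.05) noise — at the quantile
hitting the requested IR (±10% or the generator refuses).  This label
model is deliberate: positives really are the high-efficiency pairs, so
the efficiency screen has true signal to find and the directional
rebalancing test is meaningful.

Toy genomes are uniform-random backgrounds with protospacer+NGG sites
planted at recorded non-overlapping coordinates on either strand, with a
requested number of substitutions; the truth table lists the expected
candidates.

What the synthetic conditions do **not** establish: real datasets have
correlated loci, sequencing artifacts, cell-type-dependent chromatin
effects and label noise that the generator does not model, and the
shipped score table is synthetic rather than a published one.  Passing
the directional tests shows the pipeline's machinery behaves as designed
under controlled signal, not that any particular benchmark number is
reproduced.

## Problem sizes in the test suite

The rebalancing-benefit experiment uses 20,000 records (10 guides ×
2,000) at IR 1000, a 5 kb toy genome planting each guide's on-target
site plus two 1-mismatch decoys (so the specificity screen has competing
loci), and a compact network configuration (4 filters/branch, d_model
16, 8 heads, dense 32→2, 7-epoch cap, training-loss monitor) across five
generator seeds — sizes chosen so the full suite runs on a single CPU in
minutes while leaving the experiment's conditions (imbalance, sample
size, signal structure) intact.  The genome-scan oracle check runs ~100
seeded genomes of 1.5–12 kb at mismatch tolerances 0–2.

## Known limitations

* ESB is undefined for bulge-aligned records, by construction.
* The balanced/mild severity boundary is heuristic (see above).
* The specificity aggregate and the on-target-by-sequence exclusion rule
  are conventions; both are isolated behind single functions.
* The NumPy network is desk-scale: fine for the package's record sizes
  (10^4–10^5 × 24 × 7), not a GPU training stack.
* The D9 benchmark IR is 213883/50 = 4277.66 exactly; one published
  rendering of it differs by 0.01 (and a CVIR value appears truncated
  rather than rounded) — the package reports the exact arithmetic.
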