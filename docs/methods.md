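# Methods

## Problem and model

Saliva-secretory protein identification is treated as binary sequence
classification. The input representation is an L × 20 evolutionary profile —
a position-specific scoring matrix (PSSM) from an iterative profile search —
or, absent profiles, a one-hot encoding. The classifier is a multilane 1D
capsule network: each lane applies a 1D convolution of a distinct kernel
size (1–33 residues), so different lanes respond to sequence features at
different length scales (single-residue composition up to long sorting
signals); a PrimaryCaps layer groups the convolution output into vector
capsules whose length encodes feature presence; and dynamic routing
aggregates the position grid into a small set of hidden capsules whose
agreement structure summarizes the whole sequence. Concatenated hidden
capsules from all lanes feed a dense layer and a 2-class softmax.

### Encoding

* Column order is the BLAST PSSM alphabet `ARNDCQEGHILKMFPSTWYV`.
* Raw PSSM scores are mapped into (0, 1) by an elementwise logistic
  1/(1+e^(−x)). Profile-generation pipelines do not document a single
  normalization convention, so the transform is a pluggable argument of
  `normalize_profile`; the logistic default is bounded, monotone and
  order-preserving.
* Inputs are fixed at `max_len` = 1000 rows. Longer sequences keep their
  first 500 and last 500 residues (secretion-relevant sorting signals
  concentrate at the termini); shorter ones are zero-padded at the end.
  `max_len` must be even; the two halves exactly tile the output, so no
  overlap handling is needed.
* Unknown or ambiguous residues (B, J, O, U, X, Z) one-hot encode to
  all-zero rows — a neutral signal rather than invented frequencies. In
  PSSM mode the file's row is used as-is.

### Network

Defaults per lane: 10 convolution filters (stride 1, 'same' zero padding,
ReLU, dropout 0.5 after this layer only), 8 primary-capsule channels of
dimension 16 built by a size-1 convolution of the filter outputs, squash
applied per capsule; 8 hidden capsules of dimension 16 reached by 5 routing
iterations. Dense layer: 128 ReLU units. Output: softmax over 2 classes,
index 1 = saliva-secretory.

Two squash variants are implemented, selectable via
`NetworkConfig.squash_variant`:

* `sabour` (default): v = (‖s‖²/(1+‖s‖²))·s/‖s‖ — monotone in ‖s‖ with
  lengths covering [0, 1). This is the form of the original dynamic-routing
  formulation that the architecture builds on.
* `as_printed`: v = (‖s‖/(1+‖s‖²))·s/‖s‖ — appears in some descriptions of
  this architecture but is non-monotone and bounded by 1/2, which
  contradicts the intent of mapping capsule lengths onto [0, 1]; it is kept
  selectable for comparability.

A norm guard ε = 1e−8 (added under the square root as ε²) makes the zero
vector map to the zero vector with finite gradients.

Routing follows the standard recipe: logits start at 0 (first-iteration
couplings are uniform), couplings are a softmax over output capsules (so
Σ_j c_ij = 1 for every input capsule at every iteration), and the agreement
update b_ij += û_(j|i)·v_j is skipped after the final iteration. The
transformation matrices W producing û_(j|i) = W_(channel(i),j)·μ_i are
shared across the positional grid within each channel, which makes the
hidden capsules near position-invariant detectors.

One stated detail of the architecture is internally inconsistent: a
PrimaryCaps stride of 9 cannot produce the also-stated 1000 × 8 primary
capsule grid. The grid size is load-bearing for routing, so the default is
`primary_stride = 1` (honoring the capsule count) with the stride exposed in
`LaneConfig` for either reading. Similarly, 'same' padding is assumed so
the primary grid length equals the input length.

### Training

Each ensemble member is optimized with Adam (learning rate 0.001, moment
decays 0.9/0.999 — the three constants that are fixed by the protocol) on
mean cross-entropy plus an L2 penalty 0.5·λ·Σ‖W‖² over weight matrices
(biases unpenalized). Hyperparameters the protocol leaves open use
conventional defaults, all exposed in `TrainConfig`: batch size 32, max
100 epochs, early-stopping patience 10 epochs on the cross-entropy of a
stratified 10% validation holdout (loss, not accuracy, is monitored),
λ = 1e−4. The best-validation weights are returned.

Backpropagation is analytic throughout, including through the unrolled
routing loop (the couplings' dependence on the logits is differentiated, not
detached); the test suite verifies gradients against central finite
differences to ~1e−8 relative error. Training runs in float32 by default
(`TrainConfig.dtype`), which roughly halves CPU cost; float64 is available
and is used wherever gradients are being verified.

### Bagging

With positives scarce (350 training positives vs 1750 negatives), each of
T = 10 bagging iterations trains on all positives plus n = 350 negatives
drawn without replacement (fresh draw per bag; positives are not resampled —
each bag is exactly 350 + 350). The ensemble output is the arithmetic mean
of member softmax outputs. `kfold_split` provides the stratified 10-fold
cross-validation harness used for within-training-set evaluation.

### Threshold selection and metrics

All six confusion-matrix metrics follow the standard formulas; MCC is the
selection criterion for the operating threshold because it is informative
under imbalance. Candidate thresholds are the midpoints between adjacent
unique scores plus sentinels beyond both extremes (making the all-positive
and all-negative policies reachable); the decision rule is score ≥
threshold; MCC ties resolve to the smallest candidate. Metrics with a zero
denominator return 0 with a flag rather than NaN so they aggregate stably
across bags. The paired t-test across bagging iterations is two-sided
(sidedness was an open choice); zero-variance nonzero differences raise a
degenerate-case error rather than fabricating a p-value.

### Ranking and enrichment

S = 2·(argmax(p) − 0.5)·max(p) ranks proteome-wide predictions in [−1, 1].
At the exact tie p = (0.5, 0.5) the argmax resolves to index 0, giving
S = −0.5; tied scores are flagged in the output. Ranking ties break by id
for determinism.

Published validation tables for this ranking protocol report the
hypergeometric **point probability** P(X = k) of the marker overlap in the
top-n list — verified by recomputing the printed cells — even though the
quantity is described as a p-value. Both statistics are implemented
(`hypergeom_point`, `hypergeom_tail`); `enrichment_table` defaults to the
point probability to match the published convention, with the upper tail
(the statistically proper enrichment p-value, and the more conservative
choice for new analyses) one argument away. Evaluation goes through SciPy's
hypergeometric distribution (log-gamma based, stable at N ≈ 20,000); the
test suite cross-checks it against exhaustive draw enumeration at small N.
One published cell (the 37-marker overlap at top 2000) is not reproducible
from its own printed inputs under either statistic and appears to be a
printed-value error; the corresponding acceptance test documents this by
failing.

## Synthetic data

The generator emulates the statistical structure the classifier exploits,
not salivary biology:

* **Positives** (default 100): background-composition sequences of length
  50–300 with a 12-residue motif implanted at the N-terminus, each copy
  mutated at 10% of positions — a degenerate sorting-signal analogue.
* **Negatives** (default 500): drawn from 25 families (sizes ~10–30); each
  family has its own Dirichlet-drawn residue composition and a signature
  5-mer, mimicking Pfam-style family structure. Negatives never contain
  the exact motif (occurrences are scrubbed).
* **Profiles**: per-position composition vectors concentrated (weight 0.8)
  on the true residue and perturbed with Dirichlet noise (concentration 30),
  imitating the conservation structure of alignment-derived PSSMs. Rows lie
  in [0, 1] by construction.

What this does not emulate: real evolutionary conservation gradients along
the sequence, realistic amino-acid background frequencies, homology between
positives, or any actual secretion signal. Passing the learnability
benchmark therefore shows that the pipeline can learn a planted terminal
signal from profile input at desk scale — not that it attains the published
real-data accuracy, which would require the original profile dataset and
full-size training.

The negative-set construction rules for real data are implemented over an
abstract family map: families under 10 members are excluded, 3 members
sampled per family, and redundancy above 30% identity removed greedily
(longest sequence first). Identity is estimated by shared 3-mer containment
over the shorter sequence — a deterministic, fast proxy for alignment
identity, adequate for fixtures; it is a stand-in for exact-identity
clustering tools and documented as such on the function.

## Scaled-down benchmark

`salicaps.experiments.synthetic_learnability` freezes the desk-scale study
conditions: the default synthetic dataset, inputs encoded at 100 positions,
a stratified 20% holdout, and a 2-lane ensemble (kernel sizes 9 and 15,
bracketing the 12-residue motif; primary stride 2 to keep the routing grid
small), T = 3 bags of all positives + equally many negatives, at most 20
epochs. On one CPU a seed runs in under a minute; the acceptance criterion
is the median held-out ROC-AUC over seeds 1–3 (measured 0.976).

## Reproducibility

Every random choice flows from explicit integer seeds: dataset generation,
bag composition, weight initialization, dropout, batch order and the
validation split all derive from NumPy `Generator`/`SeedSequence` fan-out,
so the full pipeline is bit-stable on a fixed platform. CLI runs write
manifests (arguments + input SHA-256 digests); checkpoints embed the network
configuration.

## Known limitations

* No GPU path; the full 8-lane, 1000-position model trains at CPU speed
  (minutes per epoch at realistic dataset sizes).
* The PSSM parser reads the first 20-column block of the BLAST ASCII
  dialect only.
* The redundancy filter is a k-mer heuristic, not an aligner; it is meant
  for synthetic fixtures, not publication-grade clustering.
* Calibration of ensemble probabilities is averaged, not explicitly
  calibrated; S-values are confidence rankings, not probabilities of
  secretion.
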