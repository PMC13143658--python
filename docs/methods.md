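# Methods

`cardiofuse` implements a multimodal cardiac-disease prediction pipeline:
selective median denoising of grayscale MR slices, gray-histogram threshold
segmentation of the cardiac region of interest (RoI), hand-crafted
deformation and ECG descriptors fused at the feature level, spider-swarm
feature selection with recursive elimination, and an ensemble of fuzzy-input
multilayer perceptrons. This note records the model assumptions, parameter
choices, numerical details, and the places where the design was genuinely
open.

## Selective median filtering

Impulse (salt-and-pepper) noise saturates pixels to 0 or 255. The noise mask
flags exactly those values; every other pixel is treated as clean and is
never modified. A flagged pixel is replaced by the median of the *valid*
pixels in its k×k window (k = 3 by default), itself excluded; if every
neighbour is flagged, the median of all neighbours is used. Borders are
handled by edge replication so the frame never manufactures artificial
0-valued "noise". With an even number of candidates the *lower* median is
taken, keeping the output an 8-bit integer. A `mode="full"` switch applies a
plain k×k median everywhere for comparison. The selective filter is exactly
reproducible by a nested-loop reference implementation, which the test suite
uses as an oracle.

Assumption: noise is exclusively-extreme impulse corruption. Pixels that are
legitimately 0 or 255 in clean data would be smoothed; the phantom generator
therefore clips clean intensities to [1, 254] so that planted noise is
identifiable exactly.

## Least-max-value segmentation

The segmenter thresholds at the LMV: the smallest gray level that is a local
maximum of the raw 256-bin histogram (`h[g] >= h[g-1]` and `h[g] >= h[g+1]`,
edges one-sided) with a count above the dominance threshold (default 20
pixels). If no level qualifies, a fallback threshold of 220 is used. Pixels
darker than the LMV form the RoI cluster C1 (cardiac structures are dark on
a brighter background in this convention); everything else is background C2.
By default the RoI is then reduced to its largest 4-connected component,
demoting isolated dark specks; a flag restores the raw clustering. A second
flag restricts threshold candidates to gray levels above 220, the literal
reading of the printed rule, which in practice makes C1 nearly the whole
image and is therefore off by default.

Known limitation: on a raw, unsmoothed histogram the smallest dominant local
maximum is a noisy order statistic. On the synthetic phantoms (background
200±10, RoI 80±10, 128×128) the threshold usually lands at the lower tail of
the background mode (~171-180) and recovers the ellipse with Jaccard ≥ 0.98,
but on roughly one seed in ten no early tail maximum exists and the
threshold drifts into the background mode, accreting a fringe of background
pixels (Jaccard 0.85-0.94). Mean Jaccard over seeds remains ≈ 0.984. This
sensitivity is a property of the thresholding rule itself; smoothing the
histogram would remove it but is deliberately not applied.

The phantom ellipse is also deliberately small (default semi-axes 8×6 px on
128×128): the rule only separates the modes when the RoI's per-gray-level
counts stay *below* the dominance threshold; a larger ellipse would make the
RoI mode itself the smallest dominant maximum and split the RoI in half.

## Deformation and ECG descriptors

The four RoI descriptors are the simplest measurable quantities matching
their names, and are isolated behind one module so alternates can be
swapped:

* **NAD** = |RoI| / (H·W), the area fraction;
* **ACAD** = mean absolute turning angle (radians per step) along the traced
  8-connected outer boundary of the largest RoI component (Moore-neighbour
  tracing, no sub-pixel smoothing — a contour-walk oracle can check it
  exactly: a filled r×r square gives 4 right-angle turns over 4(r−1) steps);
* **NVD** = Σ_RoI I(p) / (255·H·W), the normalized intensity mass;
* **ACVD** = mean |4-neighbour Laplacian|/255 over interior RoI pixels.

An empty RoI yields all zeros. ECG beats are fixed-length rows (187 samples
at 125 Hz, the public heartbeat-CSV layout). Peaks are samples above
mean + 2·sd with a 25-sample (0.2 s) minimum separation; heart rate is
60 / mean inter-peak interval, falling back to one beat per waveform
duration when fewer than two peaks exist. Blood pressure is an explicit
linear *surrogate* with no physiological claim:
`bp = 80 + 30·(max − median) + 0.2·hr`; the coefficients are configuration
and are echoed into output metadata. The fused sample is the fixed-order
record (nad, acad, nvd, acvd, bp, hr), pairing the artery (NAD/ACAD), valve
(NVD/ACVD) and ECG (BP/HR) feature pairs used by the impact measures.

The MRI and ECG sources are modelled as unpaired; the pipeline pairs them by
index within a class and documents that this emulates feature-level fusion,
not patient-level fusion.

## Spider-swarm feature selection

Candidate feature subsets are continuous points in [0,1]^d binarized at 0.5.
Fitness of a mask is the stratified 3-fold accuracy of a linear max-margin
classifier (standardized features, fixed internal seed) minus a cardinality
penalty λ·|mask|/d with λ = 0.01; the empty mask scores 0. The colony has
N spiders (default 20), of which `floor((0.9 − 0.25u)·N)` are female
(u ~ U(0,1)), giving the 65-90% female share observed in social-spider
colonies. Spider weights are min-max-normalized fitness. Females move under
two "vibrations" — from the nearest spider with strictly higher weight and
from the global best — with fresh U(0,1) coefficients per spider, the
attraction negated with probability 1 − ps (ps = 0.7), plus a scalar drift
δ·(u − ½). Males above the male weight median move toward the nearest
female, the rest toward the male mean position; the step coefficient toward
the target is a fresh U(0,1) draw (the source algorithm leaves it
unspecified). When every spider ties, only the drift applies. Positions are
clipped to [0,1]^d; the best spider never moves, so the best fitness is
monotone over iterations. Classical spider mating/replacement is omitted (no
specification to implement).

After T iterations (default 50) per-feature rank scores combine three
factors: the magnitude share `wei_a = mean|x_a| / Σ mean|x|` (sums to 1),
the modal-decile value weight `w_val` (fraction of samples in the feature's
most populated of 10 equal-width bins), and the swarm inclusion frequency of
the feature among the top-weight half of spiders across all iterations; the
product is min-max rescaled to [0,1].

Recursive elimination then re-examines features in ascending rank order:
removal is accepted when the fitness without the feature is at least
C1 − tol (tol = 0.005, same CV folds for both scores, so the comparison is
paired). Passes repeat until a full pass confirms every remaining feature or
a floor of 2 features is reached — single-pass elimination cannot reach the
floor on pure-noise data because between-mask fitness fluctuation
(~1-3 percentage points at n = 100) exceeds tol, and the repeated-pass
reading also matches the procedure's description. A `raw_branch` flag
switches to the literal strict comparison (`C2 > C1`) for comparison. All
fitness evaluations within one run are cached by mask, which both speeds the
run and guarantees the monotone-elitism property exactly.

No spectral computation appears anywhere in the source method despite the
name; none is implemented.

## Fuzzy perceptron ensemble

Features are min-max normalized by training extremes (test values clipped to
[0,1]). Class prototypes E(c,f) are per-class means of normalized values;
bell widths are s(c,f) = 1/(2·var + 1e-6), capped at 1e4 for single-valued
class features. The printed fuzzy layer is an *inverted* bell
Fl = 1 − 1/(1 + s(a−b)²), zero at the prototype; membership is its
complement μ = 1 − Fl so that proximity means high membership. Both are
returned and tested. Type-II sets widen μ into the interval
[μ − δ₂, μ + δ₂] ∩ [0,1] with δ₂ = 0.1 (no estimator is given for δ₂; it is
configuration). The fuzzy dependency diagnostic aggregates interval centres
(F) and half-widths (F1) with non-negative feature weights and reports
FD = F/(F1 + F); it is not on the prediction path.

The membership-to-rank mapping interpolates linearly through the anchor
pairs (0.9 → 1), (0.1 → 6), (0 → 13), clamps to rank 1 above 0.9, and
rounds half-up to an integer ≥ 1; it is monotone non-increasing and hits the
anchors exactly.

Impact measures pair the fused features per class with
D(x,y) = |x − y| + 1e-6 on normalized values:
ACIM = 100·D(x_nad, E_nad)/D(x_acad, E_acad), VCIM and ECIM analogously for
the valve and ECG pairs, and CECIM = (VCIM/ACIM)·ECIM. The CECIM-argmax rule
(ties to the lowest class index) is exposed as an alternative classifier;
the primary decision path is the perceptron ensemble, because the source
conflates the two and the ensemble is the trained component.

Each member fuzzifies every selected feature into G = dim // d bell channels
at evenly spaced prototypes in [0,1], with the width chosen so membership is
0.5 midway between adjacent prototypes, zero-padding to input widths of
exactly 128, 144 and 156. Members are two-hidden-layer (64, 32) softmax
perceptrons trained for 100 epochs at learning rate 0.001 with
adaptive-moment (Adam) updates and mini-batches of 128, 64 and 128
respectively (batches clip with a warning when the training set is
smaller). The cross-entropy loss is weighted per sample by the fuzzy
certainty κ = mean_f |2μ_f − 1|, so samples whose memberships hover near 0.5
influence the gradients less; κ = 0 when every membership is exactly 0.5 and
1 when all are crisp. The output-layer gradient is the delta rule
(pred − true) scaled by κ. The MLP is implemented directly in numpy because
the per-sample certainty weighting is part of the classifier's definition.
Prediction is a majority vote over the three members; two- and three-way
ties are broken by the largest summed softmax score. Training and prediction
are bit-reproducible from the seed.

## Evaluation protocol

Per-class precision TP/(TP+FP) and recall TP/(TP+FN) on a percent scale,
F1 = 2PR/(P+R), macro-averaged for multiclass (the averaging convention is
recorded in the report since the source states none); zero-denominator
classes score 0 with a warning. ROC AUC is the rank statistic with mid-rank
ties — exactly the probability that a random positive outscores a random
negative — averaged one-vs-rest for k > 2. Cross-validation is stratified
k-fold (default 5) with folds differing by at most one sample; feature
selection, normalization and the fuzzy profiles are all refit inside each
training fold, so a label-permutation run collapses to chance (the suite
checks chance ± 10 points). Single-split runs default to 70/30 stratified.
The ablation harness runs MRI-only, ECG-only, fused-without-selection and
the full framework on one shared split and emits a four-row metrics table
with the selected features recorded for the full row.

## Synthetic data

The generators define the study conditions; all are deterministic per seed.

* **Phantoms**: 128×128, background N(200, 10²), elliptical RoI N(80, 10²),
  default semi-axes 8×6 px, intensities clipped to [1, 254] *before* impulse
  corruption at rate p (default 0.05, salt/pepper with equal odds), so the
  corrupted pixels are exactly the ground-truth noise. "Abnormal" phantoms
  scale the semi-axes by 1.3 and add a sinusoidal boundary ripple
  (amplitude 1 px, 5 lobes). What they do not emulate: anatomy, partial
  volume, bias fields, speckle — so passing tests demonstrate the algorithmic
  contracts, not clinical performance.
* **ECG beats**: 187 samples at 125 Hz; Gaussian QRS bumps with
  class-conditional amplitude/spacing for the five heartbeat categories,
  5% amplitude jitter, additive Gaussian noise (sd 0.05). P/T morphology is
  not modelled.
* **Planted tables**: n×d standard-normal features with k informative
  columns whose class means are separated by Δ pooled standard deviations;
  the informative index set is returned for scoring recovery. The selection
  benchmark is n = 300, d = 20, k = 4, Δ = 1.5; the classifier benchmark maps
  a fully informative 6-column table (n = 400, Δ = 2) affinely onto realistic
  feature scales.

## Problem sizes in the test suite

The suite exercises the benchmarks at the sizes above. Where a property is
checked across many repetitions the swarm is run at 8-10 spiders for 6-10
iterations and the ensemble at reduced input widths/epochs — these settings
are the suite's own study sizes and are recorded in each test; the library
defaults (20 spiders, 50 iterations, 100 epochs, 128/144/156 inputs) are
unchanged.

## Reproducibility

Every stochastic component takes an explicit seed or `numpy` Generator; the
pipeline splits one master seed per stage via `SeedSequence`. Run
directories contain the resolved config, a config hash, library versions,
and no timestamps, so reruns are bit-identical. Model archives (`.npz`)
carry weights, fuzzy profiles, normalization statistics and the seed.
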