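# Methods

## Problem and coordinate conventions

The package classifies genomic locations as distal regulatory elements
(DREs) from local histone-modification signal. All coordinates are 0-based
half-open (BED convention). Signal lives on a fixed grid of 100 bp bins per
chromosome; the last partial bin of a chromosome is dropped rather than
padded, so every track has shape `floor(length / bin_size)` and windowing
arithmetic never meets a ragged edge. bedGraph gaps are read as zero signal,
consistent with treating "no histone modification signal" as all-zero
features.

## Features

The signal unit is RPKM: `reads / ((bin_len/1000) · (total_reads/1e6))`.
Replicates are combined by element-wise mean before feature extraction. A
feature window around an anchor bin spans `flank/bin_size` bins on each side
(defaults: 1000 bp flank, 100 bp bins → 20 bins), and the per-mark rows are
stacked in the fixed canonical order of the 24-mark panel to form the
(24, 20) snapshot; flattening is row-major, giving d = 480. The canonical
order itself is arbitrary but must be fixed: the CNN's first-layer kernels
span all rows, so any permutation defines an equivalent but distinct model.
Windows that would cross a chromosome edge are skipped, not padded — padding
would invent signal. Input (control) normalisation beyond RPKM is not
implemented because no formula for it is fixed by the protocol; RPKM of the
ChIP signal is used directly.

## Labels

Positives are the union of p300, TFBS and DHS peaks that are at least
1000 bp (inclusive) from every TSS, each anchored to the bin containing the
peak midpoint (midpoint floored to the grid — the convention of the
enhancer-prediction family this pipeline belongs to). Bin-level duplicates
are removed with source precedence p300 > TFBS > DHS; the precedence is
arbitrary but fixed and recorded per location. Negatives are TSS midpoint
bins plus bins sampled uniformly without replacement from the genome at
≥ 2500 bp from every DHS (the same radius as the validation gray area, so a
random negative can never be trivially "validated"); the sampler is
deterministic under its seed and reports its shortfall when the genome is
too small. Distances are always edge-to-edge, zero when intervals overlap
and infinite across chromosomes.

## Preprocessing protocol

1. **Zero filter.** Examples whose snapshot is exactly all zeros are
   removed; the test is strict equality, so a single 1e-9 RPKM value keeps
   an example.
2. **Balancing.** All positives are kept and negatives are subsampled
   without replacement to the positive count. If negatives are already the
   minority the set is left unchanged with a warning; upsampling is never
   performed. Balancing precedes splitting.
3. **Five-pair split.** After a seeded shuffle, the first 70 % forms the
   training pool and the remainder the test pool; the test pool is cut into
   five equal disjoint subsets (a remainder smaller than five is dropped).
   Each of the five training sets is an independent draw without replacement
   from the training pool — "overlapping training sets" realised as
   independent subsamples, which reproduces the variance-reduction intent
   without assuming the sets are nested. Every constructed split is checked
   for train/test location leakage at construction time.
4. **Gray marking.** Locations within 2.5 kb of a true positive marker that
   are not marker bins themselves are flagged gray; `apply_gray_labels`
   relabels them positive for training-set use only (binary classifiers
   throughout — gray is not a third class). Gray handling is applied after
   balancing, where the flag is available on every surviving example.

## Classifiers

All five models expose `train` / `predict_scores` with a real-valued score,
thresholded only by the evaluation protocol.

* **Linear SVM** — hinge-loss linear separator, penalty C (default 1).
* **Kernel SVM** — RBF kernel, C = 1, γ = 1/d by default. Tuned values for
  the SVMs and forest are not fixed by the protocol; the defaults are
  deliberately plain and the knobs are exposed in `ModelConfig.hyperparams`.
* **Random forest** — 100 trees, unlimited depth; score is the
  positive-class vote fraction.
* **DNN** — 480 → 600 → 500 → 400 → 1 with PReLU after each hidden layer and
  dropout 0.3 between hidden layers; MSE loss on {0,1} targets; RMSProp
  (lr 1e-3, ρ 0.9).
* **CNN** — conv(64 kernels, 24×2, stride 1) → PReLU → conv(64, 1×2) →
  PReLU → max-pool(1×2) → dropout 0.5 → FC 300 → PReLU → dropout 0.5 →
  FC 300 → PReLU → dropout 0.3 → FC 1; MSE loss; Adagrad (lr 1e-2). Output
  widths are 19 after conv1, 18 after conv2 and 9 after pooling. PReLU is
  also applied between the fully connected layers: the architecture
  diagrams omit activation layers only for space, and the rectifier
  between dense layers is the consistent reading.

Both networks train 50 epochs at batch size 128 by default. The output
neuron is linear — MSE regression toward {0,1} rather than a sigmoid
cross-entropy head — matching the stated loss; scores need not lie in
[0, 1]. PReLU slopes initialise at 0.25 (the value from the activation's
original formulation). Weights use He-style initialisation. Training is
single-threaded numpy and bit-reproducible given `ModelConfig.seed`, which
drives initialisation, shuffling and dropout through one generator.

## Validation-Rate evaluation

A prediction validates iff its edge-to-edge distance to the nearest true
positive marker is ≤ 2500 bp — the boundary is inclusive ("within 2.5 kb"
read inclusively) — and it does not overlap a TSS, which is known-wrong
regardless of distance (TSS override applied after the distance test).
`vr_at_n` is the validated fraction of the n top-scoring predictions, ties
broken by genomic position for determinism; `vr_curve` sweeps an ascending
grid of n. The per-pair VRs aggregate to a mean and sample SD (ddof 1).
Marker distances are answered by a sorted-array index with a running
maximum of interval ends (exact also for overlapping markers, O(log n) per
query); a brute-force all-pairs implementation is kept as the reference and
the two are asserted equal on randomized fixtures.

The full-scale controlled count is 6,000 predictions per test subset
(100,000 genome-wide predictions × 30 % test share ÷ 5 subsets). On
scaled-down synthetic runs the count must instead be chosen below the
expected number of true positives per subset — the acceptance script uses
40 per ~120-example subset and 200 on the pooled ~600-example test set —
because VR at a count exceeding the available positives is ceiling-limited
below 1 even for a perfect ranker.

Ranking uses one-tailed t-tests of H1 "mean(a) > mean(b)": paired on the
per-pair differences when models share training sets, Welch-unpaired
otherwise. Zero-variance paired differences (e.g. both models saturated at
VR 1.0 on every pair) are reported as a degenerate case, never as a number.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
ChIP-seq reads. Defaults define the study conditions: a 2 × 5 Mb genome of
100 bp bins; 1,100 planted DRE sites, 900 TSS sites and 3,000 random distal
negatives (≈ 5,000 examples at 22 % positive prevalence); background noise
drawn i.i.d. per mark-bin from a Gaussian truncated at zero (scale 1 RPKM —
RPKM is non-negative, and clipping leaves a realistic mass of exact zeros);
additive enrichment bumps of amplitude 5 RPKM shaped as a discrete Gaussian
over ±3 bins (σ = 1.5 bins) on six acetylation marks at DRE sites and four
trimethylation marks at TSS sites (the subsets are mnemonic index sets —
tests depend on their difference, not on biology); and an 8 % Bernoulli
subset of example locations whose full 20-bin window is zeroed across all
marks, emulating the no-signal samples the zero filter removes. Planted
DREs always satisfy the ≥ 1 kb distal-to-TSS rule, and the random negatives
are drawn through the labeling module's own sampler so dataset assembly
exercises the real pipeline path. An optional shift augmentation jitters
bump centres by up to ±3 bins. A track-free sampler
(`make_snapshot_examples`) draws snapshots from the same signal model
directly, for model-property probes where genome placement is irrelevant,
and `make_xor_examples` builds the XOR-structured variant: each example
carries the acetylation-group bump with probability ½ and the
trimethylation-group bump with probability ½, labelled by the XOR of the
two, so no linear functional of the features separates the classes while
kernel and convolutional models can.

What passing on this generator does *not* show: robustness to correlated
mark backgrounds, replicate batch effects, peak-width variation, mappability
structure, or the H1-cell-line mark covariances of real data. It shows the
pipeline's plumbing, determinism, metric correctness and the qualitative
model ordering (non-linear models capture interactions a linear margin
cannot).

## Problem sizes and numerical choices

The default synthetic study (~5,000 examples, ~2,000 after balancing, five
pairs of ~1,400 training / ~120 test examples, 50 epochs) was chosen so the
complete protocol for all five classifiers runs in minutes on one CPU while
keeping every per-subset count meaningful. Determinism: every stochastic
step (placement, noise, sampling, balancing, splitting, initialisation,
dropout) derives from explicit seeds; two runs with the same seeds are
identical. Ties in `top_n` break by (chrom, start); `balance_classes`
preserves input order; sample SD uses ddof 1 throughout.

## Known limitations

* No bigWig input; convert to bedGraph upstream.
* No input-control normalisation formula; RPKM of ChIP only, as discussed.
* Random-forest score granularity (vote fractions) produces many ties at
  small tree counts; the deterministic tie-break makes results reproducible
  but VR at very small n can be sensitive to it.
* The generator's marks are conditionally independent given the planted
  class; real mark panels are strongly correlated.
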