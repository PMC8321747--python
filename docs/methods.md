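# Methods

This note records the scientific and numerical choices behind `chemfuse`:
what each stage computes, which conventions were open and how they were
fixed, what the synthetic generator does and does not emulate, and the
known limitations.

## Pretreatment

**Correlation-optimized warping (COW).** Chromatograms are aligned to a
reference (by default the column-wise mean of the calibration samples) by
piecewise-linear time warping. The signal is cut into near-equal target
segments of `segment_length` points (default 50); each source segment may
stretch or shrink by up to `slack` points (default 15). Dynamic
programming over all feasible segment-boundary positions maximizes the
summed Pearson correlation of the linearly interpolated source segments
with the reference segments. The optimum is exact over that discrete
space — the test suite checks it against exhaustive enumeration on small
instances. Conventions: segment boundaries are spaced by rounding
`i·(n−1)/N`; a zero-variance segment contributes correlation 0; ties
between equally good warps are broken toward the length closest to
nominal, so aligning the reference to itself returns the identity node
map. The defaults were chosen so that a 7201-point, 60-min chromatogram
with shifts of a few points is comfortably inside the slack budget.
Alignment runs before grid reduction because shift resolution is finer on
the raw grid.

**Grid reduction.** One point in every `k` = 3 is kept, starting at the
first point: 7201 → 2401 columns.

**Savitzky–Golay second derivative** (window 15, polynomial order 2)
removes baseline offset and slope and sharpens overlapped bands. Only
full-window convolution outputs are treated as valid: the 7 edge columns
per side are discarded rather than padded, giving n − 14 columns
(2401 → 2387). The derivative is taken with respect to the axis units
(minutes or cm⁻¹).

**Band deletion** (FTIR only, after the derivative): every column whose
wavenumber lies in [1750, 2670] or [3700, 4000] cm⁻¹ — inclusive bounds —
is dropped. These regions carry ATR-crystal interference and no
absorption. Deletion runs after filtering so the derivative window never
spans a splice discontinuity. On our 1737-point grid this leaves 1098
columns; the exact count depends on the instrument's wavenumber grid and
boundary convention, so it is a property of the grid, not of the method.

## Sampling

Kennard–Stone selects n_cal = ⌊2m/3⌋ calibration samples (2:1 split):
the two mutually farthest samples first, then repeatedly the sample
maximizing the minimum Euclidean distance to those already picked. Ties
go to the lowest sample index, making the split fully deterministic. One
split is shared by every block and fusion strategy; it is computed on the
column-wise concatenation of the per-block autoscaled matrices so that
the wider or higher-variance block cannot dominate the distances.

## Classifiers

**PLS-DA.** The one-hot class matrix is regressed on autoscaled variables
(zero-variance columns dropped with a warning) by NIPALS PLS2. The
latent-variable count maximizes 7-fold cross-validated Q² = 1 −
PRESS/TSS, ties favouring fewer components; folds are deterministic
interleaves (row i → fold i mod 7) with scaling and centring refit inside
each training fold. Predicted responses are turned into membership
degrees by an affine per-sample rescale onto [0, 1] (row min → 0, row
max → 1; a constant row maps to 0.5 everywhere). That rescale is the main
interpretive choice for high-level fusion: fuzzy connectives need degrees
in [0, 1], and the rescale preserves the argmax, so hard classifications
are unaffected. VIP scores use the standard definition
VIPⱼ = √(p · Σₐ SSₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSₐ) with SSₐ the response variance
explained by component a; Σⱼ VIPⱼ² = p holds identically and is asserted
in the tests.

**Random forest.** Hyper-parameters come from out-of-bag (OOB) error
curves. A forest of `ntree_init` (default 2000) trees is grown at the
default mtry = ⌊√p⌋; the running OOB error after each tree is recorded
(a tree count only becomes eligible once every sample has at least one
OOB vote, since earlier "errors" are not comparable). n_tree is the
smallest count whose overall OOB error equals the minimum while no
class's OOB error exceeds its value at that minimum — all classes
considered at the same time. mtry is then swept over ⌊√p⌋ ± 10 (clipped
to [1, p]) at that n_tree; lowest OOB error wins, ties resolve toward the
default, then toward the smaller value. The floor convention for the
default is deliberate: √2387 ≈ 48.9, and ⌊·⌋ gives the canonical 48.
Memberships are the fraction of trees voting each class, so rows sum
to 1.

## Feature extraction

**PCA** is fitted on the calibration set only (centred on calibration
means; inputs are autoscaled per block beforehand). The component count
grows while the 7-fold cross-validated Q² of held-out-row reconstruction
gains at least 0.01 per component, capped by `max_components` and the
calibration rank. Validation rows are projected onto the calibration
loadings.

**Boruta.** Each iteration appends freshly shuffled shadow copies of all
still-candidate columns, fits a random forest, and scores every feature
by OOB permutation importance — the drop in OOB-vote accuracy when one
column is permuted, computed per tree on its own out-of-bag samples with
a single permutation per feature per iteration. A real variable beating
the best shadow registers a hit. Cumulative hit counts are tested against
Binomial(t, ½) two-sided with Bonferroni correction over the variables
still undecided; significant winners are confirmed, significant losers
rejected (and removed together with their shadows); whatever is undecided
when iterations run out stays tentative. Confirmed ∪ tentative columns
are the extracted features. Fewer than five remaining candidates stops
the run early.

*Finite-sample caveat.* "All-relevant" selection answers an in-sample
question. In a pure-noise matrix of 50 variables and only a few dozen
rows, the largest chance correlation with the labels is large enough
(≈ 0.45 at m = 40) that the corresponding variable genuinely
outperforms its shadows round after round, and Boruta — correctly, by
its own definition — confirms it. At the cohort size of the reference
design (m = 60) this essentially never happens; the null-calibration
tests therefore run at that size, and users should expect occasional
chance confirmations whenever m is small relative to the variable count.

## Fusion

Low-level fusion concatenates the pretreated blocks after per-block
autoscaling (switchable off); without it the wider block dominates any
variance-driven model. Mid-level fusion concatenates per-block extracted
features; an empty selection from one block passes the other through
with a warning. High-level fusion aggregates the per-block membership
matrices element-wise with the four connectives (max, min, average,
product); each connective votes its argmax and the class with most
operator votes wins. The vote can tie 2–2, where a plain majority is
undefined; the implemented tie-break is the higher
average-connective membership, then class order — an explicit artifact
decision, exercised directly in the tests. If every block agrees on a
sample, every connective and hence the final vote preserves that class.
High-level strategies reuse the per-block models fitted on each block's
extracted features; no separate fusion training happens.

## Evaluation

Per-class performance is the **efficiency** √(sensitivity × specificity)
from one-vs-rest confusion counts — the geometric mean reading of the
efficiency statistic; it is undefined (reported missing) when a split
contains no positive or no negative samples of the class. Total accuracy
is the percentage of correctly classified samples, reported to two
decimals. The **permutation test** refits the PLS-DA model (at the
latent-variable count chosen on the true labels) on 30 label
permutations, records each refit's R², Q², and the correlation of the
permuted one-hot labels with the originals, and fits a least-squares line
of Q² against that correlation including the original model at
correlation 1. A vertical-axis intercept at or below zero is the
no-overfitting verdict. Degenerate permutations (identical to the
original labelling) are re-drawn.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not chromatographic or infrared physics. Constituents are Gaussian peaks
with per-class mean apex heights; per-sample variation enters through
(i) relative height jitter (sd 0.08), (ii) a latent chemotype factor
(sd 0.15) shared between the two blocks of a sample and loaded on
designated peaks, (iii) a random quadratic baseline (coefficient sd
0.05), (iv) additive white noise (sd 0.02), and (v) integer retention-
time shifts (sd 3 points, LC only, applied to peak centers — giving COW a
recoverable ground truth). The FTIR intervals 1750–2670 and 3700–4000
cm⁻¹ contain no class-discriminative signal and carry 3× noise,
mimicking the chemically silent / ATR-interference regions that the
pretreatment deletes; the generator refuses peaks placed there.

The reference design has five balanced origin classes (the real cohorts
were likely unbalanced; per-origin counts are not published). Classes 3–5
carry strong markers in both blocks. Classes 1 and 2 share every marker
and differ only through a complementary pair: an LC peak with means
1.0 vs 0.8 and an FTIR band with means 0.8 vs 1.0, both loaded on the
latent factor. Within one block the latent variation (sd 0.15) masks the
0.2 offset (separation ≈ 1.2 sd → roughly a quarter of class-1/2 samples
misassigned); the difference of the two peaks cancels the latent factor
and doubles the offset (separation > 3 sd), so the classes are confusable
per block and cleanly separable jointly. This is what gives fusion — and
specifically feature-selected mid-level fusion — something real to gain,
and it is the structure behind the headline comparison in the test suite.

Ground truth: a variable is *informative* when the between-class range of
the noiseless class-mean fingerprint is at least 20 % of the largest such
range; the same rule applied to the pretreated noiseless means yields the
reference sets used to score Boruta's recovery.

What the generator does **not** emulate: real peak-shape asymmetry and
co-elution, heteroscedastic detector noise, multiplicative scatter,
instrument drift between sessions, unbalanced cohorts, and any real
triterpene chemistry. Passing tests therefore demonstrate that the
pipeline's statistics behave as designed under the assumed structure, not
that a particular accuracy would be reached on instrument data.

## Problem sizes

Generator defaults keep the instrument grid (7201 LC points over 60 min;
1737 FTIR points over 650–4000 cm⁻¹), and the pretreatment width checks
run at that size. The multi-seed experiment suites use a reduced grid —
721 LC / 433 FTIR points with 12 samples per class — which preserves the
peak-to-grid geometry (peak widths scaled with the grid) while keeping a
five-seed, seven-strategy, two-classifier sweep in the minutes range, and
`RunConfig.quick()` (300 initial trees, 150 Boruta trees, 40 Boruta
iterations) is the matching protocol scale. All methodological settings —
split ratio, folds, SG window, bands, connectives, mtry sweep — are
identical at both scales.

## Known limitations

* PLS-DA memberships are ipsative (per-row rescaled): they rank classes
  within a sample but are not calibrated probabilities across samples.
* The running-OOB n_tree rule depends on the bootstrap stream; two
  forests with different seeds may legitimately pick different n_tree.
* COW complexity grows with slack × signal length; full-size alignment
  of many samples is the slowest stage (a few seconds per chromatogram).
* The 2–2 fuzzy-vote tie-break and the 0.01 Q²-gain rule for PCA
  components are fixed conventions where the underlying procedure is
  underdetermined; both are isolated behind single functions.
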