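# Methods

This note documents the models, conventions and design choices behind the
package, including the places where a convention had to be fixed because the
underlying definitions admit variants.

## Color spaces

All five spaces are device-dependent (no illuminant knowledge needed) and
are returned as 8-bit planes so every descriptor consumes channels
uniformly:

* **HSV** — hexcone model; H is rescaled from [0, 360°) to [0, 255], S and V
  to [0, 255]. Achromatic pixels (max = min) take H = 0, S = 0.
* **YCbCr** — ITU-R BT.601 full-range (JPEG convention), Cb/Cr offset by 128.
  Note that some libraries use the studio-swing variant (Y in 16–235); the
  full-range form is used here so the planes span the whole 8-bit range.
* **I1I2I3** — Ohta's decorrelated components; I2 and I3 are shifted by
  +127.5 before rounding so all planes share [0, 255].
* **RnGnBn** — chromaticity coordinates 255·C/(R+G+B); a black pixel maps to
  (85, 85, 85), the limit along the achromatic axis, avoiding a 0/0.

Planes are rounded to nearest (ties to even, the IEEE default) and clipped.
Hue is treated as an ordinary 8-bit channel downstream; its circular
topology is not given special treatment.

## Cooccurrence descriptor (RSCCM)

Channel values are requantized to Q levels by `floor(v·Q/256)`. The
neighborhood is the isotropic 8-neighbor set at infinity-norm distance δ
(the four directions 0°, 45°, 90°, 135°, both senses), which makes the
matrices orientation-insensitive and within-component matrices exactly
symmetric; directional 2-pixel neighborhoods are supported via the
`offsets` argument but are not part of the standard grid. Pairs whose
neighbor falls outside the image are skipped and normalization divides by
the number of pairs actually counted, so no padding artifacts enter the
statistics. Only the 6 unordered channel pairs are computed: with a
symmetric offset set, the matrix of (g', g) is the transpose of (g, g') and
carries no extra information.

Haralick statistics use log base 2, `0·log 0 = 0`, and the convention
correlation = 0 when a marginal standard deviation vanishes (degenerate
matrices). "Homogeneity" `Σ p/(1+|i−j|)` and the inverse difference moment
`Σ p/(1+(i−j)²)` are kept distinct; the literature sometimes conflates
them. The information measures of correlation follow the common convention
of base-2 entropies with `sqrt(1 − exp(−2(HXY2 − HXY)))` for the second
measure, and the first measure is defined as 0 when max(HX, HY) = 0.

## Opponent LBP descriptor (EOCLBP)

Neighbor p of P sits at angle 2πp/P from the east axis, counter-clockwise
in image coordinates, at radius δ; positions are **pre-sampled** — rounded
to the nearest pixel (ties to even), with no bilinear interpolation. Bit p
has weight 2^p and the threshold is ≥ (ties produce 1), the standard LBP
convention. Codes are computed for all pixels at distance ≥ δ from every
border, so a histogram always sums to (H−2δ)(W−2δ). All 9 ordered channel
pairs are computed; between-component pairs (g, g') and (g', g) are genuinely
different operators here (center and neighbors swap channels).

### The 17 histogram statistics

The first-order statistics of the code distribution p(v) are mean, median,
mode (smallest code on ties), standard deviation, and two spread measures:
the interquartile range Q3−Q1 and the interdecile range P90−P10, with
quantiles defined as the smallest code reaching the target cumulative
probability. The published description of this feature set names "two
interquartile ranges" without defining them; the IQR/IDR pair used here is a
documented stand-in — two well-defined, distinct spread measures.

The second-order statistics are likewise a documented stand-in for an
"adapted Haralick" construction whose original definition is not publicly
specified: the first 11 Haralick formulas (energy, contrast, correlation,
variance, IDM, sum average, sum entropy, entropy, difference variance,
difference entropy, homogeneity) are evaluated on the product measure
q(i,j) = p(i)p(j) over code values. Because q factorizes, every feature
reduces to closed forms in the marginal and its sum/difference
distributions, which are obtained by FFT convolution — the 2^P × 2^P matrix
is never materialized (for P = 16 it would have 4.3·10⁹ entries). A test
verifies the FFT path against a dense product-measure evaluation on small
histograms. Under the product measure the correlation feature is
identically 0; such constants are deliberately tolerated and removed by the
zero-variance screen of the selection stage.

## Feature bank

Columns follow a fixed canonical order — space-major, then descriptor
(RSCCM before EOCLBP), then component pair, then setting, then feature
name — so extractions are bit-stable and column provenance (encoded in CSV
headers as `RSCCM|HSV|C1C2|d2q64|contrast`) uniquely identifies each
feature's configuration. Images smaller than 2δmax+1 per side are rejected
rather than padded: padding would contaminate the descriptor statistics.

## CEFS

* **Zero-variance screen.** Constant features (possible by construction,
  see above) are removed before anything else; Pearson correlation is
  undefined for them.
* **Standardization.** By default features are z-scored (training
  statistics) before correlation, trace and 1-NN computations, because the
  bank mixes heterogeneous units (entropies in bits, code ranges up to
  65535, probabilities). This is a package choice — the published procedure
  does not state a normalization — and is switchable (`standardize=False`).
* **Clustering.** Edges link features with |ρ| strictly above t; clusters
  are connected components, so transitively ("long") dependent features
  share a cluster. The threshold grid is {0.75, 0.80, 0.85, 0.90, 0.95};
  the winning t maximizes the cluster-quality trace computed in sample
  space, where B weights each cluster's mean-sample deviation by its
  cardinality and W accumulates within-cluster deviations, both scaled by
  1/D. Ties resolve to the largest threshold (finest partition). The
  cluster-quality computation is O(N³ + N·D); fine for N up to a few
  thousand samples.
* **Trace inversions.** (W+B) is regularized with a relative ridge
  1e−8·trace(W+B)/dim before solving, with a pseudo-inverse fallback;
  duplicated features and N < D make exact singularity routine. The ridge
  keeps the documented identities (Tr = 0 for coincident means;
  0 ≤ Tr ≤ min(dim, N); invariance under invertible transforms) accurate to
  well below 1e−6 in well-conditioned cases.
* **Selection loop.** Greedy forward search on the class-separability trace
  (between-class scatter with equal class weights — a mild generalization to
  unbalanced classes — and within-class scatter scaled by 1/N); ties in the
  candidate argmax resolve to the smallest column index. After each
  addition the added feature's whole cluster leaves the candidate pool, so
  selected features are pairwise cluster-disjoint by construction.
* **Dimension choice.** After each step, the mean validation accuracy R̄_d
  of 1-NN/L1 over K stratified folds × r repetitions (defaults K=3, r=10) is
  recorded; d̂ is the argmax over d = 1..dmax, smallest d on ties. All fold
  randomness derives from the single run seed. Default dmax = 100 caps the
  learning time; tests and the desk-scale experiments use dmax = 15–30,
  matched to their much smaller candidate pools.

## Classifier

1-NN with the L1 (city-block) distance — no parameters, so evaluation
reflects the representation. Distance ties resolve to the smallest
training-row index. Stratified folds come from scikit-learn's
`RepeatedStratifiedKFold` (per-class proportions within ±1 sample per fold).

## Synthetic data

`make_texture_dataset` renders each class as an oriented sinusoid plus an
orthogonal second component and a noise field, mixed across the three
channels by a class-specific matrix: classes therefore differ in spatial
frequency (spacing 0.012 cycles/px starting at 0.08), orientation (spread
over π) and inter-channel correlation — the three properties the descriptors
measure. Within-class variation comes from per-image random phases,
frequency jitter (12% relative), orientation jitter (±20°, typical of
uncontrolled acquisition) and strong additive noise (sd twice the signal
amplitude). The defaults deliberately sit in a low-SNR, high-variation
regime: there, no single descriptor configuration suffices (single
predetermined configurations score ~30–85% on the 4-class benchmark below)
and combining configurations pays — the regime the method exists for. What
these textures do **not** emulate: natural image statistics (1/f spectra,
edges, albedo variation), illumination changes, or the visual appearance of
real bark/wood datasets; passing tests demonstrate the pipeline's
correctness and the combining-beats-prior-choice effect on controlled
structure, not field performance.

`make_planted_bank` draws feature banks with known ground truth: informative
columns (class-mean ladders separated by 2 sd, independently permuted per
feature), redundant copies (parent + N(0, 0.1) noise, correlation ≈ 0.995)
and independent noise columns. Defaults (N=60, 3 classes, 6 informative × 4
copies + 90 noise = 120 columns) put the selection stage under realistic
redundancy pressure.

## Desk-scale experiment sizes

The combined-vs-single comparison runs 10 seeds of: 4 classes × 20 images
(10 train / 10 test) at 64×64, a reduced grid of 2 color spaces (RGB, HSV),
4 RSCCM settings ((1,32), (2,64), (3,32), (5,64)) and 4 EOCLBP settings
((8,1), (8,2), (8,3), (8,5)) — 1848 features — with CEFS at dmax=30 against
all 16 single predetermined configurations evaluated without selection.
These sizes were chosen as the smallest that exercise every mechanism
(multiple spaces, descriptors, scales, redundancy) while keeping the whole
suite quick to run; the compact hybrid matched or beat the best single
configuration in 9 of 10 seeds in the run recorded in the test suite.

## Known limitations

* The second-order histogram statistics and the two spread ranges are
  principled stand-ins (see above), not a reproduction of an external
  definition.
* Cluster quality is O(N³); CEFS as a whole is intended for N up to a few
  thousand training samples.
* Greedy forward selection with cluster removal is not globally optimal;
  it trades optimality for speed exactly as designed.
* Hue wrap-around is ignored (H is a linear 8-bit channel), which slightly
  penalizes reddish textures spanning the hue origin.
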