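# Methods

This note documents the models, estimators and design choices behind
`plantsig`, in the spirit of a statistical package's methods
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

Classify the chemical stimulus (NaCl, H₂SO₄, O₃) applied to a plant
from windows of its electrical signal. The practical difficulties the
package addresses are (i) extreme class imbalance — in the motivating
dataset the ozone class holds ~94 % of the ~38 000 windows, so any
unweighted metric or single split is dominated by one class — and (ii)
feature engineering for short (1024-sample, 10 Hz) noisy biosignal
windows, where higher-order and nonlinear statistics carry the
discriminative information that first-order statistics do not.

## Synthetic signal generator

No raw recordings are deposited anywhere public, so the pipeline is
exercised on synthetic blocks. The generator is *not* a biophysical
model of action or variation potentials; it reproduces only the
statistical structure the analysis machinery assumes:

* Per class, a block is `mix_ar·AR(1)(φ, σ) + mix_fgn·fGn(H)` passed
  through `x → x + c·x²`. The AR(1) component sets short-range
  correlation and variance, the fractional Gaussian noise (exact
  Davies–Harte circulant-embedding synthesis) sets the long-range
  dependence that DFA and R/S respond to, and the quadratic map adds
  controlled asymmetry for the odd-moment features.
* Defaults (NaCl φ=0.30 σ=1.00 H=0.55 c=0; H₂SO₄ φ=0.60 σ=1.40 H=0.70
  c=0.12; O₃ φ=0.45 σ=0.80 H=0.62 c=0.05) are free choices, **not**
  estimates of real plant signals: they make every class pair differ
  in at least two generating parameters while keeping univariate
  feature histograms strongly overlapping, which is the regime the
  methodology is designed for. Default class counts 60/144/3426 keep
  the real study's ≈10:24:571 imbalance ratio at one tenth scale.
* The species label (tomato/cabbage) is an independent Bernoulli(0.5)
  draw, so species can never confound stimulus — matching the observed
  near-complete overlap of species-wise feature histograms in this
  kind of data. The classifiers never see it.
* One master `SeedSequence` spawns a substream per block, so output is
  bit-identical for a given config regardless of generation order.

Consequences for interpretation: passing end-to-end tests show that the
*pipeline* ranks separable configurations above chance and is correctly
calibrated at chance on permuted labels; they say nothing about
attainable accuracy on real plant recordings, and the generator's
Gaussian-driven, stationary blocks lack real-data features such as
nonstationary bursts, electrode artifacts and stimulus-onset
transients.

`reference_signal` additionally provides processes with closed-form
feature values used as extractor oracles: iid Gaussian noise
(DFA α = 0.5, Hjorth mobility √2, flat wavelet spectrum), fGn (α = H,
lag-1 autocorrelation 2^{2H−1}−1), random walks (α = 1.5), sinusoids
(mobility 2·sin(πf/f_s), P_s = A²/2, correlation dimension 1) and
constants.

## Preprocessing

* **Drift removal** — 2nd-order Butterworth high-pass, cutoff 0.05 Hz,
  applied forward–backward (`sosfiltfilt`, zero phase, length
  preserved). The original study used a separately published "optimal"
  IIR design whose procedure is not reproduced here; the configurable
  Butterworth is a documented stand-in, and with 1024-sample
  post-stimulus windows the choice mainly needs to kill DC and slow
  ramps (tested properties).
* **Windowing** — non-overlapping `floor(N/L)` blocks, trailing
  remainder discarded.
* **Outlier rule** — per feature, quartiles by linear interpolation;
  default band is the literal asymmetric condition
  (Q₁ − n·IQR, Q₁ + n·IQR) with n = 6 (`rule="as_printed"`), with the
  conventional (Q₁ − n·IQR, Q₃ + n·IQR) band available. A row is
  dropped if *any* feature violates its band or is non-finite; a
  zero-IQR feature degenerates to an equality band (with a warning).
  Pipeline order is extract → outlier-filter → min–max normalize:
  normalizing after removal prevents extreme rows from compressing the
  [0, 1] scale. Retention as a function of n is exposed as
  `retention_curve`.
* **Normalization** — per-feature min–max to [0, 1]; constant features
  are an error naming the column.

## Features

All fifteen features are deterministic functions of the block. Choices
where conventions genuinely differ:

* Variance is the population (÷N) second central moment. γ₃…κ₆ are
  *standardized* central moments E[(x−μ)^k]/σ^k (Gaussian reference
  0, 3, 0, 15); raw central 5th/6th moments are scale-dependent and
  meaningless after rescaling, so the standardized reading is used and
  documented. Kurtosis is reported raw (Gaussian = 3), not excess.
* Fano factor is literally σ²/μ; on near-zero-mean (filtered) blocks it
  is numerically wild, which is intentional — |μ| < 1e−12 flags NaN and
  the IQR stage absorbs the instability. This mirrors the original
  design where the outlier filter removed ~10 % of rows.
* DFA: integrate the mean-removed series, linear detrending, ≥10
  log-spaced box sizes in [4, N/4], α = slope of log F(n) vs log n.
* Hurst: classical R/S over log-spaced window sizes in [8, N/2],
  averaging R/S over the segments of each size; zero-variance segments
  are skipped. R/S has a known small-sample upward bias on white noise
  (tests allow up to 0.62 for true 0.5).
* Wavelet-packet entropy: full db4 decomposition to level 3 (8 leaf
  bands), Shannon entropy of normalized leaf energies in nats, bounded
  by ln 8.
* Spectral power: (1/N)Σx², i.e. mean periodogram energy by Parseval.
* Correlation dimension: Grassberger–Procaccia with delay embedding
  m = 5, τ = 1, correlation sum on a 20-point log radius grid spanning
  [1 %, 50 %] of the attractor diameter, slope fitted over the middle
  third of the grid. All-equal embeddings give 0 by convention.
* Degenerate blocks yield NaN for the affected features inside the
  table pipeline (so the cleaning stage handles them) but raise
  informative errors when the individual estimator is called directly.

The exact parameterizations of the toolkit used by the original
authors are unpublished; every setting above sits in `FeatureConfig`
and is overridable.

## PCA

Full-rank PCA of the (min–max-scaled, not z-scored) features; sign
convention: largest-magnitude loading element positive. Component
count = smallest k whose cumulative explained-variance ratio reaches
the threshold (default 0.90). In the benchmark, PCA is refit on each
draw's training half and applied to its test half — the leakage-free
default — while `pca_global=True` reproduces a single whole-dataset
fit, since which of the two the original analysis used is ambiguous.

## Monte Carlo under-sampling benchmark

Per draw: (1) sample the minority-class count from every class without
replacement (the minority class enters whole; with the motivating
counts 628/1488/35718 this yields 628×3 = 1884 rows); (2) stratified
50:50 split (⌊n/2⌋ per class to train — 314/314 at study scale);
(3) optional per-draw PCA; (4) fit each classifier, record the 3×3
test confusion matrix. Draws are independent; *within* a draw all
classifiers and both feature spaces share the same indices (common
random numbers), which is what makes the paired "repeated-measure"
MANOVA reading meaningful. Reproducibility flows from one master seed
through per-draw and per-classifier `SeedSequence` substreams.

The ten classifier configurations are pinned scikit-learn estimators,
kept verbatim from the benchmarked settings even where unusual:
AdaBoost uses a depth-5 tree base, 600 estimators and learning rate 50
— far outside typical ranges; in practice the boosting weights
overflow and training stops after a few rounds, which is faithful to
the benchmarked configuration and flagged here. The installed
scikit-learn (≥1.6) provides only SAMME-type discrete boosting, the
real-valued SAMME.R variant having been removed upstream; this is the
one place the pinned configuration cannot be matched exactly. The
linear-kernel SVM's gamma = 1.5 is set but inert, as printed.
Hyperparameter optimization is deliberately out of scope.

`average_confusion` row-normalizes every matrix before averaging, so
the reported mean confusion matrix is on a 0–1 scale with unit row
sums.

## Metrics

For a 3×3 count matrix C: accuracy = mean per-class recall
(= trace/total only on balanced test sets — a tested identity);
balanced accuracy = macro mean of (Sen_k + Spe_k)/2 one-vs-rest;
F_β = macro mean of (1+β²)·Pre·Rec/(β²·Pre + Rec) with F_k = 0 when
Pre + Rec = 0; MCC per Gorodkin with 0/0 → 0. Macro (unweighted)
averaging is used throughout: under the balanced under-sampling design
class weighting is moot. Chance levels differ by metric: 1/3 for mean
per-class recall, 1/2 for the sensitivity/specificity balanced
accuracy, 0 for MCC — the permutation tests assert each at its own
level.

## MANOVA

W and B are the standard within/between scatter matrices; the test
eigenvalues are those of W⁻¹B (computed by direct solve + `eigvals`,
negatives below 1e−10 clipped, truncated to s = min(p, g−1)). The four
trace statistics follow the textbook identities (V = Σλ/(1+λ) etc.);
for s = 1 they obey V = U/(1+U), Λ = 1 − V, Θ = U — the identity the
published tables' printed values satisfy and the acceptance script
recomputes. F approximations: Rao's formula for Wilks, the standard
Pillai approximation, the SAS/McKeon approximation for
Hotelling–Lawley, and the upper-bound F for Roy; for q = 1 (two groups
or one sample) all four reduce to the exact Hotelling T² F with
df (p, ν_e − p + 1). These match `statsmodels.multivariate.MANOVA`
(an independent implementation used as a cross-check oracle in the
tests, never as the computation itself).

The "repeated-measure" comparison is provided in both defensible
readings: (a) per-group one-sample location tests (Hotelling T² cast
as λ = T²/(n−1)), which is what the published per-group table rows
correspond to, and (b) a paired test on the per-draw 15D − 7D
difference vectors, valid because of the common-random-numbers design.
The effect-size column R² is reported as V/s. Degrees of freedom are
reported from the dimensions actually used (p = 3 metrics); the
published tables print df1 = 2 with three dependent variables,
consistent with a rank-deficiency drop in the original software — the
package does not imitate that, and the acceptance targets exercise
only the rank-robust λ → statistic identities. Near-singular W (e.g.
when metric triples are almost collinear at very small R) raises an
error advising de-duplication rather than returning garbage
eigenvalues.

## Problem sizes in the tests

The test suite and examples run the generator at reduced scale —
counts 40/96/400 (536 blocks) for the end-to-end benchmark with R = 50
draws and k-NN, 300–1000 replicates for the statistical calibration
checks — chosen as the smallest sizes at which the asserted tolerances
(e.g. chance-level mean per-class recall within 1/3 ± 0.05 over 50
draws, MANOVA type-I error within 0.05 ± 0.02 over 1000 replicates)
are comfortably stable. The full-scale design (counts 628/1488/35718,
R = 1000, all ten classifiers, both spaces) runs through the same code
path via `plantsig run-all`.

## Known limitations

* The synthetic generator's defaults are package choices, not fitted
  to real plant data; absolute metric levels on synthetic data carry
  no information about field performance.
* The drift-removal filter is a stand-in for the original optimal IIR
  design.
* AdaBoost's SAMME.R variant is unavailable in current scikit-learn
  (see above).
* The R/S Hurst estimator inherits the classical small-sample bias;
  DFA is the more accurate of the two scaling-exponent features at
  N = 1024.
* MANOVA assumes approximate multivariate normality and homogeneous
  covariances of the metric triples; with R = 1000 draws the tests are
  robust to moderate violations, but the per-draw metrics of a
  near-perfect classifier are bounded and strongly collinear, where
  the error surface above applies.
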