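# Methods

This note documents the models, algorithms, parameters and numerical
choices implemented in `neuromap`, the conditions its synthetic data
emulates, and the limits of what its tests demonstrate.

## Preprocessing

All recordings are standardized before embedding:

* **Resampling** to 200 Hz by polyphase rational resampling
  (anti-aliased, `scipy.signal.resample_poly`).
* **Filtering**: a 2nd-order IIR notch at 60 Hz (Q = 30) followed by a
  4th-order Butterworth bandpass 0.5–40 Hz, each applied
  forward-backward for zero phase. Filtering twice changes passband RMS
  by under 2%, so the pipeline is practically idempotent.
* **Bipolar re-referencing** to the four-channel montage F3-C3, C3-O1,
  F4-C4, C4-O2. A missing electrode is a hard error naming the label.
  EDF channel-label dialects are normalized by stripping an `EEG `
  prefix and `-REF`/`-LE` suffixes, case-insensitively.
* **Segmentation** into non-overlapping 10-s windows from t = 0
  (half-open intervals, 0-based start times); a trailing remainder is
  dropped.

**Multitaper spectrograms.** Each segment channel becomes a
time–frequency log-power image: 1-s windows with 50% overlap, 3 DPSS
tapers at time-bandwidth NW = 2, FFT zero-padded to twice the window
(0.5 Hz bins), restricted to 0.5–40 Hz, log10 with a floor of 1e-10.
This yields a 4 × 80 × 19 stack per segment — large enough to resolve
the rhythms that define the classes, small enough for a CPU-scale
network. Window length, overlap, taper count and band are all
configurable; the defaults are this package's choice, as is the
per-channel z-scoring of each log-power image before the network
(recorded in the training config and disableable).

## Synthetic EEG

The generator defines the study conditions for every test and for the
acceptance script. It makes no claim of clinical realism: classes are
designed to be *spectrally separable*, which is the property metric
learning needs, and the note below each design states what real data
would add.

* **Class segments.** Eleven recipes over a white-noise floor:
  W = 10 Hz alpha, posterior-dominant (attenuated on the frontal
  pairs); N1 = mixed 4–7 Hz theta; N2 = theta plus 13 Hz spindle bursts
  gated ~1 s in 3; N3 = high-amplitude 0.5–2 Hz delta (75 µV);
  REM = low-amplitude mixed 5/7.5 Hz; GRDA/LRDA = 2.5 Hz rhythmic delta
  (60 µV), generalized vs left-pair-only; GPD/LPD = 1 Hz biphasic sharp
  transients (80 µV), generalized vs left-pair-only; SZ = a 3→8 Hz
  chirp with amplitude ramping ×0.4→×1.5; BS = the burst-suppression
  generator with a fraction drawn from U(0.3, 0.7). Frequencies within
  a band and phases are randomized per segment; everything is
  deterministic given (class, seed).
* **Burst suppression.** Alternating epochs: suppression = Gaussian
  noise σ = 1.5 µV (envelope well below the 10 µV criterion), bursts =
  50 µV 4.3 Hz + 25 µV 9.1 Hz oscillations plus noise. Epoch plans are
  jittered but keep epochs ≥ 0.6 s wherever the target fraction
  permits, so detection minima do not clip them; the realized
  suppressed-time fraction is within 0.02 of the target by
  construction. Up to three suppression epochs per 10 s bound the
  envelope-dilation bias of the detector (see below) to ≈ 0.015.
* **Cohorts.** Each synthetic patient is a first-order Markov chain
  over the 11 classes with transition matrix P = (1 − s)·1πᵀ + s·I,
  where π is the group's stationary occupancy and s ∈ [0, 1) a
  *stickiness* that lowers the realized transition entropy while
  leaving occupancy unchanged. Occupancy and dynamics are therefore
  independently plantable — the two axes the prognosis analysis uses.
  Outcomes are "good"/"poor"; centers are assigned round-robin
  (default 5). With `signals=True` the matching EEG is synthesized by
  concatenating class segments (used by the end-to-end smoke path; the
  statistical prognosis tests run on the label sequences directly,
  which keeps them fast and targets exactly the planted quantities).

What passing tests on this data do *not* show: robustness to artifacts,
electrode noise, inter-patient spectral variability, ambiguous or mixed
patterns, or label noise — all properties real cohorts have and this
generator deliberately omits.

## The embedding network

A Siamese inception-style CNN maps a 4 × 80 × 19 spectrogram stack to a
unit vector in 128-D. Each inception block runs four parallel branches
— 1×1, 3×3 and 5×5 convolutions plus 3×3-average-pool → 1×1
convolution — concatenates them (4 × base filters channels) and applies
ReLU; blocks are separated by 2×2 average downsampling. The head
averages over the *time* axis only, pools the frequency axis into 8
coarse bands, and maps linearly to the embedding dimension, followed by
explicit L2 normalization. Full global average pooling was rejected by
design: it makes the representation translation-invariant in frequency,
erasing absolute band position — precisely the feature that separates
EEG rhythms — whereas time-averaging preserves it while keeping the
head small.

Presets: `tiny` (1 block, 8 base filters, ≈ 34k parameters; used by
tests) and default (3 blocks, 16 filters, ≈ 142k). The network and its
gradients are hand-written numpy (NHWC layout, im2col + BLAS matmuls;
the backward pass is validated against central finite differences in
the test suite). Training uses Adam (lr 1e-3), batches of 64 triplets,
margin α = 0.2 (the convention of the face-recognition literature the
loss comes from), uniform random triplet mining (anchor class uniform
over classes with ≥ 2 segments, negative class uniform over the rest —
no hard-negative mining), and early stopping when the relative
epoch-loss improvement stays below 1e-3 for 5 consecutive epochs. All
randomness flows from a single config seed; identical configs reproduce
identical loss histories.

## Map geometry and evaluation

* **Class medians** are elementwise medians per class, deliberately not
  renormalized onto the sphere: cosine distance is scale-free, so
  renormalization would change nothing measurable.
* **Cosine distance** d(u, v) = 1 − û·v̂ ∈ [0, 2]; on unit vectors
  d = ‖u − v‖²/2 (checked numerically).
* **MDS** is classical Torgerson scaling (double-centering +
  eigendecomposition), chosen because it is exact — to rotation,
  reflection and numerical precision — for distance matrices realizable
  in the target dimension; signs are fixed deterministically. Iterative
  stress-majorization variants were rejected since they cannot meet the
  1e-6 round-trip bound the tests impose.
* **Classification** is a patient-level k-fold (default 5) RBF SVM with
  class-balanced weights on standardized embeddings; folds never split
  a patient. The confusion matrix is row-normalized per fold and
  reported mean ± SD. One-vs-rest ROC/PR curves are bootstrapped 50×
  per fold on the test items; CIs are 2.5/97.5 percentiles of the
  pooled bootstrap values. Youden thresholds (max sensitivity +
  specificity − 1, ties toward higher sensitivity) are chosen on the
  *training* folds and applied to test folds.

## Sphere grid

Grid points start as i.i.d. standard-normal draws projected to the
sphere and are evened out by repulsive relaxation: each point moves
along the unit tangential direction of the summed inverse-square
repulsion, then is renormalized. The step decays geometrically from 0.1
to 0.001 rad over 200 iterations. For n ≤ 2000 forces use all pairs and
a backtracking line search keeps the total inverse-distance (Riesz)
energy non-increasing; larger grids use k-nearest-neighbor truncated
forces (k = 10) without the energy guarantee. Uniformity is scored by
the coefficient of variation of nearest-neighbor distances, recorded
before and after. Known limiting cases are recovered: two points become
antipodal, six points in 3-D approach the octahedron (min pairwise
distance √2). Nearest-coordinate assignment is an exact blocked linear
scan under cosine distance with ties to the lowest id — no approximate
index, so the brute-force oracle is the implementation's own contract
at every size. Grids much beyond ~10⁴ points are computationally
expensive in this exact formulation.

## Burst suppression ratio

Suppression detection on a 200 Hz channel: amplitude envelope =
sliding 50 ms maximum of |x|; candidate suppressions are maximal runs
with envelope < 10 µV; runs shorter than 0.5 s are discarded; remaining
gaps shorter than 0.2 s are merged into the flanking suppressions. The
rule *order* (threshold → discard → merge) is fixed and matters in edge
cases: a short suppression flanked by sub-0.2 s bursts is discarded,
not merged. BSR = suppressed time / segment duration, averaged over the
4 channels. The envelope's max-filter dilates bursts by up to 25 ms per
boundary, biasing BSR slightly low (≈ 0.005 per boundary at 10 s).

Categories: BSR > 0.7 suppression-dominant, 0.35 ≤ BSR ≤ 0.65
intermediate, BSR < 0.3 burst-dominant, with the two gaps left
unclassified. Some sources band the same thresholds by burst
proportion instead; `bsr_category(..., invert=True)` flips the
orientation for comparison studies. The 10 µV criterion is absolute
(microvolts), not relative — scaling a signal across the threshold
flips its classification, by design.

## Trajectories and prognostication

A recording becomes one embedding per 10-s segment (temporal order
preserved), symbolized by nearest class median or nearest grid
coordinate (cosine distance, ties to the lowest index). Features are an
extensible registry; always computed from the symbol sequence: the 11
class occupancies, time in BS / healthy (W, N1, N2, N3, REM) / IIIC
states, transition entropy, transitions per hour, distinct symbols,
dwell-time mean/SD/max, and Lempel–Ziv-76 phrase count (Kaspar–Schuster
algorithm, validated against an independent exhaustive parser). With
embeddings available: distance-to-healthy mean/min/SD (per time point,
the minimum cosine distance over the five healthy medians — the
aggregation is this package's definition), mean cosine distance to each
median, path length, and step-size moments. Transition entropy is the
first-order Markov entropy rate H = −Σᵢ πᵢ Σⱼ Pᵢⱼ log₂ Pᵢⱼ with the
empirical transition matrix and the empirical distribution of positions
1..T−1; unvisited states contribute zero, so constant and strictly
alternating sequences both score 0.

Outcome classification (good = CPC 1–2 vs poor = CPC 5; CPC 3–4
excluded) uses an RBF SVM on standardized features with patient-level
k-fold or leave-one-center-out folds; decision scores are pooled across
folds, the AUROC CI is a 1000-resample percentile bootstrap, and
sensitivity/specificity are read at the pooled Youden point. The LDA
search enumerates every 2- and 3-feature combination, scores each by
pooled cross-validated AUROC of the LDA discriminant, and ranks
descending (ties broken lexicographically for determinism); singular
covariance skips the combination with a warning. Group occupancy
comparisons use two-sided Mann–Whitney U tests.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen as this package's
defaults: 200 segments/class × 11 classes for metric learning (tiny
preset, 6 epochs, 3 seeds), 500-point grids in 128-D, cohorts of 100
patients per outcome group at 0.5 h each, and a miniature end-to-end
smoke cohort. All randomness is seed-derived; the full CLI pipeline run
twice with the same seeds produces byte-identical numeric outputs
(single-threaded numpy arithmetic, deterministic seed trees, no hidden
global state).

## Known limitations

* The synthetic classes are far more separable than real EEG; the
  saturated classification scores on fixtures characterize pipeline
  correctness, not expected clinical performance.
* The numpy network is CPU-bound and desk-scale by design; it is not a
  route to training on large clinical corpora.
* Exact (non-truncated) grid relaxation scales quadratically in n;
  very fine grids should use the k-NN force mode and accept the lack of
  an energy-monotonicity guarantee.
* The feature registry implements the three headline trajectory
  features plus ~20 standard symbolic/spatial dynamics measures; it is
  extensible but not an exhaustive classical-time-series battery.
* EDF support covers the common 16-bit continuous case (integer
  sampling rates, whole-second records) — sufficient for fixtures and
  typical clinical exports, not a full implementation of the standard.
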