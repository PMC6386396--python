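# Methods

## Model

The package implements a feed-forward hierarchy of alternating **sparse-coding
(S) layers** and **pooling (C) layers** operating on cochleograms of speech.
Each S layer carries a dictionary of `m` bases `b_j`, tensors of shape
`k x k x u` (`k = 10` by default, `u` = number of input maps), learned by
L1-regularized sparse coding on patches drawn at random from the layer input:

    minimize_{B, r}  sum_k || x_k - B r_k ||_2^2 + lambda || r_k ||_1
    subject to       || b_j ||_2 <= 1 .

Learning uses the online (mini-batch) dictionary-learning algorithm
(`sklearn.decomposition.MiniBatchDictionaryLearning`, `alpha = lambda / 2`
because sklearn puts a factor 1/2 on the quadratic term), with early stopping
disabled so the requested number of passes over the patch stream actually
runs; dead atoms are re-seeded from random data patches and all atoms are
returned at exactly unit norm.  Because the online updates can stall in
merged-atom local minima, learning restarts from three different
initializations and keeps the solution with the lowest sparse-coding
objective on a patch subsample (the k-means `n_init` idiom).  An L2-regularized variant
(`lambda * sum ||r||_2^2`, alternating ridge coding and least-squares
dictionary updates projected onto the unit ball) is provided as a control.

Encoding is convolutional: each basis is correlated with the layer input
(stride 2 in the first two S layers, stride 1 above), giving `m` feature
maps.  A slower reference encoder solves the lasso per sliding patch with
the learned dictionary fixed; it is used for sparseness measurements and for
oracle comparisons, never for the main pipeline.  C layers pool each map
over overlapping 2x2 windows with stride 1 (max by default; average and
pass-through variants are controls), so a C map has one fewer row and column
than its S source.

**Receptive-field arithmetic.**  Starting from one input sample, each S
layer adds `(k - 1) * jump` to the receptive-field side, each pooling layer
adds `(pool - 1) * jump`, and `jump` multiplies by every stride passed.  For
the default 12-layer architecture (kernels 10, conv strides 2,2,1,1,1,1,
pooling 2/1 after every S layer) this yields side lengths
10, 12, 30, 34, 70, 74, 110, 114, 150, 154, 190, 194 for S1..C6 — a 10 ms
window at S1 growing to 194 ms at C6 at the 1-ms frame step.

**Layer normalization.**  The cochleogram and every S-layer output are
rescaled to unit RMS over the training corpus before being passed upward.
Without this, the raw energy scale of the front end makes a given `lambda`
crushing at the first layer and negligible above it; with it, `lambda = 1`
(the default) exerts a comparable, moderate sparsity pressure at every
layer.  The scales are stored with the fitted model and re-applied when
encoding new inputs.

**STRF composition.**  The STRF of an S1 unit is its basis.  For a deeper S
layer, each slice of the unit's basis is nearest-neighbour-expanded by the
cumulative product of the conv strides below that layer, zero-padded by one
pixel for the pooling offset, convolved (full mode) with the corresponding
lower-layer STRF, and summed over slices.  With 2x2/stride-1 pooling the
nearest-neighbour expansion plus the single-pixel pad reproduces the
receptive-field arithmetic exactly (side `k*J + 1 = (k-1)J + 1 + (pool-1)J`),
including the worked 3x3-bases/2x2-slice/ratio-2 example that composes to a
7x7 STRF.  C-layer units inherit the STRF of their S-layer map.  On a purely
linear stack (stride 1, no pooling) the composition equals the network's
exact input gradient, which the tests verify by impulse probing.

STRFs are summarized by the rank-1 SVD factors (spectral and temporal
profiles, signs fixed so each profile's largest-magnitude element is
positive).  Center frequency and best temporal modulation are the profiles'
energy peaks; bandwidth and duration are the smallest contiguous window
around the peak containing 90% of the squared-profile energy (ties expand
symmetrically), converted to Hz via per-channel widths and to ms via the
frame step.  Because the model is convolutional, a map's STRF is
position-free; population histograms are therefore normalized to [0, 1] by
the maximum per parameter, so absolute placement on the frequency axis does
not affect them.  "Spectral modulation" (for the modulation trade-off
scatter) is the peak of the spectral profile's magnitude spectrum in cycles
per channel span — a convention, since no standard definition exists for
composed dictionaries.

## Selectivity statistics

A **unit** is one feature map at the analysis layer; its per-frame response
is the maximum absolute activation over the frequency axis of the map, and
its **response amplitude** for a phoneme instance is the maximum of that
stream over the frames whose receptive-field onset falls inside the
instance.  **Active units** respond more strongly to 1,000 randomly sampled
speech frames than to silence frames (one-sided rank-sum, p < 0.001).  The
**phoneme selectivity index** of a unit for phoneme p counts the other
phonemes whose amplitude distribution is statistically smaller (one-sided
rank-sum, p < 0.01, no multiple-testing correction); with P phonemes it is
bounded by P - 1 (32 for the 33-phoneme default).  Rank-sum tests use exact
enumeration for tie-free samples below n = 20 and the midrank-corrected
normal approximation otherwise.  Units and phonemes are clustered by
agglomerative (Ward, Euclidean) clustering of PSI vectors; the **F-ratio**
of a layer is the between- over within-group variability of the active
units' PSI vectors.

F-ratios are only meaningful where units actually differentiate phonemes:
at the lowest layers every unit ranks phonemes in nearly the same
(energy-driven) order, PSI vectors are almost identical, and the
within-group variance collapses, making the ratio numerically unstable.
Depth comparisons therefore use layers whose receptive fields span at least
~30 ms (S2 and up in the compact profile; S3 and up in the full profile).

**Lifetime sparseness** is `S = 1 - (E[r])^2 / E[r^2]`.  For the
sparseness-selectivity sweep the expectation is taken over the magnitudes of
the layer's sparse-coding responses (lasso codes of the retrained bases on a
random patch sample) — the quantity `lambda` directly regularizes.  The
convolutional responses' sparseness is dominated by the input statistics and
barely moves with `lambda` on the synthetic corpus, so it cannot carry the
sweep.  The sweep retrains only the target S layer's dictionary per
`lambda` (lower layers fixed), re-encodes, and tabulates mean unit
sparseness against the layer F-ratio.  The default grid spans 0.001-10; far
above 10 (at unit-RMS layer scale) the codes are identically zero and the
statistic degenerates.

## Acoustic decoding

Per-instance parameters: F0/F1/F2 are the median of the per-frame
ground-truth tracks over the instance (NaN for unvoiced instances); the
spectral peak is the center frequency of the maximum-energy cochleogram
channel within the instance; VOT comes from the token table (an LPC
formant tracker is included as non-normative plumbing for real recordings).
The decoder is ordinary least squares `y = w.x + b` on unit response
amplitudes, 20-fold cross-validated (seeded shuffle, contiguous blocks); a
test prediction is **correct** when its absolute error is below the RMSE of
the model on its own training split.  The chance decoder draws uniformly
between the training split's min and max of `y` and is scored with the same
per-fold thresholds; significance is a two-sample t-test over the per-fold
accuracies.  With Gaussian residuals matching the training RMSE the linear
decoder's accuracy approaches `erf(1/sqrt(2)) ~ 0.683`, which the tests
verify at n = 2,000.  A raw-cochleogram baseline flattens a 170-ms
onset-aligned window per instance and runs through the same decoder.

## Formant dynamics

Each instance's F1 (or F2) ground-truth track is resampled to T = 50 points
(the contours need a common length; 50 points at typical 100-250 ms tokens
keeps sub-5-ms resolution) and averaged per phoneme.  PCA across phonemes
(mean-centered — the conventional choice, and the one that makes the
principal components interpretable as contour-shape axes) gives PC1, whose
sign is fixed by its largest-magnitude element; the **temporal variation
index** of a phoneme is the projection of its centered contour onto PC1.
The TVI variance equals PC1's eigenvalue.  Unit encoding of formant
dynamics is the Pearson correlation between a unit's mean response per
phoneme and the TVIs.

## Synthetic corpus

The generator emulates continuous read speech as a sequence of labeled
phoneme tokens from an inventory (default 33) spread over four classes
(40% vowels, 20% each plosives/fricatives/nasals):

* **vowels** — impulse-train excitation at F0 (95-240 Hz) through
  second-order resonators at time-varying F1 (320-850 Hz) and F2
  (up to 2.3 kHz) with linear-ramp contours, 100-250 ms;
* **nasals** — the same source with a low, flat F1 (200-350 Hz) and a weak
  high F2, 60-150 ms;
* **plosives** — a silent voice-onset-time gap (10-80 ms) followed by a
  20-ms band-shaped burst at a 1.5-6 kHz spectral peak, 60-120 ms;
* **fricatives** — resonator-shaped noise with a 2-7 kHz peak, 80-200 ms.

Tokens are separated by 20-80 ms of explicit silence (guaranteeing silence
frames for the active-unit screen), normalized to equal RMS, and jittered by
per-token multiplicative lognormal factors (log-sd 0.05 by default) applied
independently to F0, formants, VOT and spectral peak — this produces the
within-phoneme parameter distributions the selectivity and decoding stages
require.  Vowel and nasal formant targets are snapped to harmonics of the
token's F0 so the formant peak exists in the excitation spectrum and the
cochleogram's energy peak recovers the ground-truth formant to within one
channel (the generator's recoverability invariant).  Ground truth records
the realized (jittered) per-frame F0/F1/F2 and per-token VOT/spectral peak.

What the generator does **not** emulate: coarticulation between tokens,
speaker variability beyond parameter jitter, prosody, higher formants, or
any claim of correspondence to a specific real phoneme inventory.  Passing
tests on this corpus demonstrate that the implementation computes the
intended statistics and reproduces the architecture-level numbers and
qualitative contrasts; they do not certify performance on natural speech.
One consequence is visible in the layer statistics: synthetic phonemes are
more spectrally separable at low layers than natural ones, which compresses
the depth gradient of the F-ratio relative to a natural corpus.

## Front end

194 fourth-order gammatone channels (scipy's IIR design), center
frequencies ERB-rate-spaced from 73 to 7,630 Hz inclusive; per channel the
output is half-wave rectified, smoothed by a 2nd-order Butterworth lowpass
at 100 Hz, and sampled every 1 ms.  The exact filter shapes of the original
cochlear model are not reproduced; the downstream analysis is agnostic to
filter minutiae.  Energies are non-negative; optional log(1+x) compression
is off by default.

## Profiles and problem sizes

Two configuration profiles are built in.  The **full** profile is the
12-layer architecture with map counts 100..500.  The **test** profile used
throughout the test suite and the trend analyses is a 4-layer network
(S1-C1-S2-C2, maps 32/32/48/48), trained with 2,000 patches per layer and
2-3 epochs on a ~200-token corpus with a 12-phoneme inventory — sizes chosen
so a full analysis cycle runs in minutes on one CPU core.  Trend claims
(depth, pooling, sparseness, decoder-vs-chance) are evaluated as medians
over at least three corpus seeds at this scale.  The depth trend alone uses
a 6-layer variant (S1..C3, maps 32/32/48/48/64/64): its lowest and top
analysis layers (S2, C3) straddle an S-layer transition, which is where the
selectivity gains concentrate — a 4-layer net's two analysis layers differ
by a single pooling stage, a contrast smaller than seed noise.

## Numerical choices and degenerate inputs

* Patches and codes are not mean-centered (the cochleogram is non-negative;
  the paper-level formulation has no centering).
* Convolution uses valid mode; full mode appears only inside STRF
  composition.
* Max pooling returns values only (no argmax bookkeeping).
* `f_ratio` returns `inf` when within-group variability is exactly zero
  with distinct group means, and 0 when the group means coincide.
* All-zero response streams make lifetime sparseness undefined (raised);
  constant decoding targets make the chance decoder trivially correct
  (accuracy 1, warned).
* Fold splitting drops instances with undefined (NaN) targets before
  assignment; rank-deficient decoding designs use the minimum-norm
  least-squares solution.
* Every stochastic stage takes an explicit seed; fitted results, pipeline
  artifacts and manifest hashes are byte-identical across reruns with the
  same configuration.

## Known limitations

* The hierarchy is purely feed-forward; no feedback, recurrence, spiking,
  or Dale's-law constraints.
* STRF "center frequency" for a convolutional map is a pattern-internal
  convention rather than an absolute tonotopic location.
* The depth trend of the F-ratio on the synthetic corpus is flatter than on
  natural speech (see the corpus section); the compact profile's two
  analysis layers (S2, C2) differ by one pooling stage only.
* The L2-regularized control uses a custom alternating minimizer with a
  fixed iteration budget, adequate for contrasts but not tuned for speed.
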