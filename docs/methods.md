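# Methods

## The problem

A remote diagnostic service should be able to classify a brain image as
tumor or normal without ever holding the plaintext image. Position-permutation
ciphers make this possible in a weak-but-useful sense: they destroy the
spatial arrangement (so the ciphertext cannot be read by a human) while
leaving the multiset of pixel intensities intact (so global statistical
structure remains learnable). This package implements the two standard
permutation ciphers of the image-scrambling literature, a controlled
synthetic test bed, and the classification pipeline that operates entirely
in the encrypted domain.

## Ciphers

**Generalized discretized Baker map.** The key is an ordered partition
(n₁, …, n_k) of the grid side N. Validity requires Σnᵢ = N and each nᵢ | N;
the second condition is enforced at validation because N/nᵢ and
s mod (N/nᵢ) must be integers for the map to be well defined on the index
grid. With offsets Nᵢ = n₁ + … + n_{i−1} (N₁ = 0), the strip of columns
Nᵢ ≤ r < Nᵢ + nᵢ maps as

    r′ = (N/nᵢ)(r − Nᵢ) + s mod (N/nᵢ)
    s′ = (s − s mod (N/nᵢ)) / (N/nᵢ) + Nᵢ

The row formula divides exactly — (N/nᵢ) always divides s − s mod (N/nᵢ) —
so the implementation uses integer arithmetic only; no floating point
touches an index anywhere in the cipher path, which is what makes round
trips bit-exact. The coordinate convention is (r = column, s = row),
0-based, so keys partition vertical strips; all correctness properties
(bijectivity, round trip, conservation) are convention-independent. The
permutation is materialized once as an N²-entry lookup table whose
bijectivity is verified at construction, then applied for a configurable
number of rounds (default 1; the composition of r rounds is precomputed by
table composition, and encrypting with rounds a then b equals encrypting
with a+b).

A single-part key (N,) is the identity map. `random_baker_key` therefore
excludes it (for N > 1) when drawing keys: parts are sampled uniformly from
the proper divisors of N until the partition completes, which always
terminates because 1 divides N.

**Arnold cat map.** (r, s) → (a·r + b·s, c·r + d·s) mod N with the
classical matrix (1, 1; 1, 2) by default; any integer matrix is accepted if
gcd(ad − bc, N) = 1, checked per grid size. t iterations are applied as the
t-th matrix power mod N (square-and-multiply on Python integers, so no
overflow), and t = 0 is the identity. The period — the smallest P with
M^P ≡ I mod N — is found by iterating matrix powers; it is exactly the
multiplicative order of M in GL₂(ℤ/N), and the test suite checks it against
an independent brute-force oracle for every N ≤ 64, plus the hand-verified
P(2) = 3.

**Conservation and diagnostics.** Both ciphers only move pixels, so the
intensity histogram and its Shannon entropy are exactly invariant — the
tests assert integer-exact equality, not approximate. The
`adjacent_correlation` diagnostic reports the Pearson correlation of a
seeded random sample of horizontally or vertically adjacent pixel pairs;
smooth images sit near +1, well-scrambled ones near 0. A constant image
makes the correlation undefined; it is reported as NaN with an explicit
degeneracy flag rather than silently as 0. One subtlety worth documenting:
a *single* round of the Baker map with the all-2 key largely converts
horizontal adjacency into vertical source adjacency, so the horizontal
correlation alone barely drops while the vertical one collapses; the
scrambling claim is therefore evaluated on the direction-averaged |r|,
which drops robustly for both ciphers.

## Phantoms

The generator emulates a small clinical study set — 251 images, 97 normal
and 154 tumor (tumor = positive class "yes") — with geometric phantoms:

| parameter | default | meaning |
|---|---|---|
| side | 224 px | image side (square, 8-bit) |
| brain_radius_frac | 0.8 | brain ellipse semi-axes / (side/2) |
| background_level / brain_level | 20 / 120 | dark field and brain interior intensity |
| gradient_amplitude | 30 | peak-to-trough of a zero-mean ramp across the brain, random direction |
| lesion_uplift | U(50, 70) | additive intensity of the single tumor lesion |
| lesion_radius_frac | U(0.10, 0.25) | lesion radius / brain radius |
| noise_sigma | 10 | additive Gaussian noise, clipped to [0, 255] |

Tumor phantoms contain exactly one lesion, rejection-sampled to fit
entirely inside the brain ellipse; normal phantoms contain none. The
uplift of ~60 over a lesion of a few hundred to a couple of thousand
pixels, against sigma-10 noise, makes the classes strongly separable —
deliberately so, since the package's central claim is about what survives
*encryption*, not about the hardness of the underlying detection problem.
The uplift is the separability dial: as it approaches zero the two
class-conditional intensity distributions converge (a tested property).

Generation is a pure function of (spec, seed). The stratified train/test
split assigns each class round(count × test_fraction) test images — at the
default 0.2 this gives 19 + 31 = 50 test images — with membership drawn
from the same seeded stream.

What the phantoms do **not** emulate: MRI physics (bias fields, k-space
artifacts, partial voluming), anatomical variability beyond ellipse
jitter, 3-D structure, or the intensity statistics of any particular
scanner. Passing results here show that the pipeline's machinery is sound
and that permutation encryption preserves learnable class structure; they
do not certify clinical performance on real MRI.

## Backbone and classifier

The feature extractor is a frozen convolutional network with its
classification head removed; images are resized to 224×224 (anti-aliased)
and scaled to [0, 1] first. The first-class backbone, `tiny`, is a
three-block network (3×3 convolutions with 16/32/64 channels, ReLU, 2×2
max pooling) whose filters and biases are fixed He-initialized draws from
a seeded generator — random convolutional features, a long-standing
baseline that needs no pretraining and runs in milliseconds per image on
one CPU (convolution is implemented as im2col + matrix multiply). The
random *biases* matter: they place each channel's ReLU threshold at a
different level, so pooled activations act as a bank of soft intensity
thresholds — precisely the nonlinear, permutation-stable statistics that
distinguish "contains very bright pixels" from "does not".

Feature reduction is global average pooling by default (64 dimensions for
`tiny`, position-agnostic and hence robust across cipher keys) or
flattening (channels × 28², position-sensitive — the right choice when one
*wants* the representation to depend on which key scrambled the image, as
in the key-mismatch experiment). The VGG16/VGG19 layer tables are encoded
so their output dimensionalities are derived analytically (512 pooled,
25088 flattened at 224 px); running them requires pretrained weights that
cannot be obtained without a download, and requesting them raises an
explicit error directing the user to `tiny`.

The head is a multilayer perceptron — ReLU hidden layers (default 256, 64)
and a softmax over the two classes (for two classes the logistic output it
reduces to is mathematically identical) — trained with mini-batch Adam
(default 30 epochs, batch 16, learning rate 10⁻³) on standardized
features. Training is an explicit epoch loop around scikit-learn's MLP so
that per-epoch loss and accuracy are logged, a non-finite loss raises an
error naming the offending epoch, and the whole fit is bit-reproducible
given the seed. Prediction returns probability rows that sum to 1 and hard
labels by argmax with ties broken toward the lowest class index.

## Pipeline

A single master seed is fanned out via seed-sequence spawning into
independent sub-seeds for the data, cipher-key, backbone-filter and
classifier stages, so stages remain individually reproducible and two runs
of the same config produce byte-identical metrics CSVs. Stage failures
abort with the stage name; artifacts written before the failure are kept.

Encryption order: the cipher contract (exact decryptability of stored
ciphertext) only survives if resizing happens *before* encryption, since
interpolation does not commute with permutation. The default is therefore
resize → encrypt; an `paper_order=True` flag applies encrypt → resize
instead for comparison, at the cost of exact invertibility of the stored
encrypted images.

The cipher-comparison harness runs the identical experiment (same dataset,
split, backbone filters, classifier initialization) once per scheme —
plaintext baseline, Baker, Arnold — so the resulting table isolates the
effect of the cipher.

## Metrics

Standard binary definitions with tumor as positive: TP = actual-positive ∧
predicted-positive, FP = actual-negative ∧ predicted-positive, FN =
actual-positive ∧ predicted-negative, TN = the rest. (Presentations of
this confusion layout in the applied literature occasionally transpose the
FP/FN cells; the four metric formulas are only mutually consistent under
the standard definitions, which is what is implemented.) Accuracy,
precision, recall and F1 are evaluated exactly as rationals of the counts;
zero-denominator precision/recall is reported as 0 with an explicit flag.
Because published binary results do not always state their averaging,
positive-class (default), macro and support-weighted variants are all
available — under class imbalance the weighted variant can exceed
accuracy, which resolves the otherwise-puzzling pattern of precision and
F-score above accuracy sometimes seen in published tables.

## Problem sizes and numerical choices

The default experiment is the full emulated study: 251 images at 224 px.
Unit tests exercise the same code paths at sides 32–64 with 50–100 images,
which keeps the whole suite under a minute while the acceptance-scale
checks (exhaustive composition sweeps, 100-image round trips, the
251-image experiment) run in tens of seconds. The exhaustive Baker oracle
covers all ~7,000 divisor-compositions for N ∈ {2, 4, 6, 8, 12, 16};
periodicity is brute-forced for N ≤ 64.

Degenerate inputs are rejected loudly rather than patched: non-square or
out-of-range images, partitions that do not divide the side, singular
Arnold matrices mod N, single-class training sets, empty confusions.
Ties and conventions are fixed and documented: lowest-class-index argmax
tie-break, "no" < "yes" class ordering, (column, row) cipher indexing.

## Known limitations

- Permutation ciphers are weak cryptography: the histogram is public, and
  known-plaintext attacks recover the key. The package is a test bed for
  encrypted-domain *learnability*, not a security product (no diffusion
  stage, no keystream, no cryptanalysis battery).
- The phantom experiment shows learnability under strong, permutation-
  invariant class signal; real MRI class signal is subtler and partly
  spatial, where the choice of feature reduction would matter much more.
- Pretrained VGG backbones are specified but not runnable offline; the
  `tiny` backbone is the supported path.
- The backbone is frozen by design; fine-tuning under encryption is out of
  scope.
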