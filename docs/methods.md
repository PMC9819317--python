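# Methods

## Type-2 fuzzy contrast enhancement

A grayscale image with intensities g on 0..L−1 is treated as a fuzzy set:
each pixel's membership in "bright" is

    μ(g) = (g − g_min) / (g_max − g_min),

where g_min and g_max are the observed extremes. A type-1 membership commits
to a single value per pixel; a type-2 set instead carries an interval of
plausible memberships, here parameterised by a single exponent α ∈ (0, 1]:

    μ_upper = μ^α ,   μ_lower = μ^(1/α) .

On [0, 1], t^p decreases in p, so μ_lower ≤ μ ≤ μ_upper, with equality at
α = 1 (the type-1 limit). The interval is collapsed with the Hamacher
T co-norm (a parametric fuzzy union)

    S_λ(a, b) = (a + b + (λ − 2)·a·b) / (1 − (1 − λ)·a·b) ,

with λ ∈ [0, 1] taken as the mean of the fuzzified map, so a globally darker
image (small λ) unions more disjunctively. S_λ satisfies S(a,0) = a,
S(0,b) = b, symmetry, and maps [0,1]² into [0,1]; since S(a,b) ≥ max(a,b),
mid-range memberships are pushed up and the histogram spreads — measured on
the synthetic images, the standard deviation of the enhanced channel rises
by roughly 25 % at α = 0.9 and is never below the α = 1 value.

Defuzzification is the linear rescale g_enh = round(g_min + μ_enh·(g_max −
g_min)) with round-half-up, so pixels at the extremes are exact fixed
points. Constant images are rejected with an explicit error (the membership
is undefined), rather than passed through, to surface misuse early.

Colour handling: fundus vasculature and lesions contrast most strongly in
the green plane, so the default is to enhance the green channel only;
luminance and independent per-channel modes are available. λ and α are
logged per image for auditability.

**Parameters.** α (default 0.9): smaller α widens the membership interval
and strengthens the union's push toward 1; α = 1 is a near-identity. λ is
computed from the image by default but can be pinned.

## The trigonometric activation

The activation is

    f(x) = x / cos(x) = x·sec(x) ,   f′(x) = (cos x + x sin x) / cos² x .

Key properties (all asserted in the test suite): f(0) = 0 and f′(0) = 1
exactly; f is odd and f′ even; f′ > 0 on (−π/2, π/2), so f is strictly
increasing there; and f(x) ≥ x for x ∈ [0, π/2) since sec x ≥ 1. Unlike
sigmoid or tanh, the derivative is bounded *below* by 1 on the working
interval — the vanishing-gradient regime cannot occur — at the price of
poles at ±π/2.

**Pole handling.** `safe_forward` clamps the pre-activation to
[−x_max, x_max] with x_max = 1.5 by default (just inside π/2 ≈ 1.5708);
outside the clamp the subgradient is 0 (a straight clamp, not a
straight-through estimator — the simplest contract, and the one the
backward pass implements). The *training registry* uses a tighter clamp,
x_max = 1.2: at 1.5 the clamped output reaches x/cos x ≈ 21.2 and the local
slope ≈ 313, and once one layer saturates its huge outputs push the next
layer past the clamp as well — instrumented runs showed deep layers at
97–100 % saturation (zero subgradient) and training collapsing on a
substantial fraction of seeds. At 1.2 the output is bounded by ≈ 3.3, the
slope by ≈ 12, and the cascade does not occur.

An alternate reading of the same symbol string, f(x) = x·cos(x) (derivative
cos x − x sin x), is registered as `proposed_xcos` for comparison; it is
non-monotone beyond |x| ≈ 0.86 and is not used by default.

**Reference registry.** tanh, the logistic sigmoid 1/(1+e^−x), ReLU, LReLU
(slope 0.01), ELU (α = 1), SELU (α ≈ 1.6733, scale ≈ 1.0507), Swish x·σ(x)
and Mish x·tanh(softplus x), each with an analytic derivative. Every
registered derivative is validated against central differences (h = 10⁻⁶,
tolerance 10⁻⁵) on a dense grid; points where a derivative is discontinuous
(ReLU/LReLU/SELU at 0) are excluded, since a central difference straddling a
kink estimates neither one-sided slope.

## Network and training

Architecture: 32×32 single-channel input (green plane of colour images;
area-interpolated resize on the way in; intensities mapped to [−0.5, 0.5]),
four blocks of (3×3 stride-1 same-padded convolution → activation → 2×2
stride-2 max-pool) with channel widths (4, 8, 16, 32), then flatten →
dense(64) → activation → dense(5) → softmax, trained with categorical
cross-entropy. Parameter count is the closed form Σ (9·c_in + 1)·c_out over
convolutions plus (n_in + 1)·n_out over dense layers (≈ 15 k parameters at
the defaults) and is asserted against the built network. Activations are
parameter-free, so swapping them changes no shapes or counts.

The widths were chosen deliberately small: on 100–250 image datasets a
wider net (8, 16, 32, 64) was markedly less stable under the steep
trigonometric activation and gains nothing in accuracy at this scale.

**Optimisation.** Nadam (Adam with Nesterov momentum), β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁸, batch size 32, 30 epochs, initial learning rate 10⁻²
by default. Three stabilisers, all exposed as estimator parameters:

- *Linear warmup* over the first 3 epochs. Without it, Nadam's early steps
  (≈ lr per parameter while the second-moment estimate is tiny) routinely
  killed every ReLU unit at lr = 10⁻² (loss pinned at ln 5).
- *Cosine decay* of the learning rate to ~0 across the run
  (`lr_schedule="cosine"`; `"constant"` preserves the plain behaviour).
  With a constant 10⁻² the training accuracy oscillated between 0.26 and
  0.95 across seeds; with the decay it settles at 0.92–1.00.
- *Global gradient-norm clipping* at 1.0, guarding against the steep-slope
  spikes of the trigonometric activation.

Weights are Glorot-uniform; biases zero. Training is plain mini-batch SGD
over a seeded permutation each epoch; everything is float64 NumPy with no
threading, so a fixed seed gives bitwise-identical histories. A non-finite
loss (the cross-entropy has no epsilon floor, so a true-class probability
underflowing to 0 yields +inf) raises a divergence error naming the epoch
and learning rate rather than silently producing NaN weights.

Predicted grades are the argmax of the softmax row; NumPy's argmax breaks
ties toward the lowest class index.

## Synthetic fundus generator

Each image (64×64 RGB by default, downsampled to 32×32 for training so the
resize path is exercised) contains: a circular retina disc on a dark
background; a bright optic-disc blob near the rim; four smooth random-walk
vessel curves (dark, width ≈ 1 px); and grade-dependent lesions —
microaneurysm-like dark dots (σ ≈ 1.3 px) and exudate-like bright blobs
(σ ≈ 2 px), placed uniformly inside the disc but clear of the optic disc.
Gaussian pixel noise (sd 4 on the 0..255 scale) is added, lesions and
vessels live mostly in the green channel (as in real fundus photographs),
and two corner pixels pin the full 0..255 range so fuzzification is always
well defined. Everything is a pure function of (config, grade, seed) via a
`SeedSequence`, so datasets are hash-stable.

Lesion counts per grade are drawn from ranges whose totals are disjoint
(0, 3–5, 10–13, 19–24, 32–39 for grades 0–4), and lesion sizes are large
enough to survive the 2× downsample. Consequently the grade is decodable
from lesion burden alone — a depth-4 decision tree on the lesion-pixel
count alone exceeds 80 % test accuracy — which is the property the CNN
experiments rely on.

**What this does and does not show.** The generator emulates the *structure*
of the grading task (ordinal lesion burden, vessel clutter, green-channel
dominance), not the statistics of real fundus photographs: no illumination
fields, camera vignetting, pigmentation variation, or lesion morphology
beyond Gaussian blobs. Passing tests demonstrate that the pipeline is
implemented correctly and can learn a lesion-count signal at desk scale;
they say nothing about clinical performance on real imagery.

## Metrics

For the 5-class problem every scalar metric is macro one-vs-rest: per class
c, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
TP/(TP+FP), F1 the per-class harmonic mean — averaged unweighted over
classes. Per-class values with a zero denominator (class absent) contribute
0 and the class index is reported in `flagged_classes`. AUC is the macro
one-vs-rest ranking AUC (trapezoidal, mid-rank ties, via scikit-learn);
it is invariant under strictly monotone transforms of the scores. Loss is
the mean categorical cross-entropy of the supplied probability rows
(floored at 10⁻¹² here, since stored predictions may contain exact zeros).

The sweep harness runs the full cartesian grid (activations × epochs ×
learning rates × batch sizes × seeds), records one row per run, marks
diverged runs as failed rows instead of crashing, aggregates cells as the
mean over seeds, and renders activation-by-grid-value tables rounded
half-even to two decimals. Default grids are desk-scale (a single epoch
count, three learning rates); larger grids are plain config values.

## Problem sizes and numerical choices

Defaults throughout are sized for a single CPU: 125–250 images of 64×64,
30-epoch runs (seconds each), sweeps of ≲ 10 cells. Tolerances: membership
algebra and T co-norm identities at 10⁻¹²; analytic-vs-numeric gradients at
10⁻⁵ with h = 10⁻⁶; probability rows sum to 1 within 10⁻⁶. Degenerate
inputs (constant images, empty grids, labels outside 0..4, spatially
collapsing pool stacks) raise typed errors naming the condition.

## Known limitations

- The trigonometric activation requires the clamp; with aggressive learning
  rates and no schedule it can still saturate an entire layer (zero
  subgradient everywhere), which manifests as a training plateau, not an
  error.
- The NumPy network is desk-scale: no GPU path, no parallel data loading;
  wall-clock grows linearly with image count and channel widths.
- Sigmoid at depth 6 with these learning rates fails to learn the synthetic
  task (vanishing gradients) — expected, and part of the motivation for the
  steeper activation, but worth knowing when reading sweep tables.
- The generator's 85/15 split is stratified by construction; it does not
  model label noise or grader disagreement.
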