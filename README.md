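# fundusdr

Type-2 fuzzy contrast enhancement and a trigonometric-activation CNN for
five-grade diabetic-retinopathy (DR) screening on fundus images.

Diabetic retinopathy is graded 0 (no DR) to 4 (proliferative) by the burden
of retinal lesions — microaneurysms (small dark dots), hemorrhages, and
exudates (bright lipid deposits). This package implements, end to end and on
CPU, a classification pipeline aimed at that grading task:

1. **Type-2 fuzzy contrast enhancement.** Pixel intensities g are fuzzified
   to memberships μ = (g − g_min)/(g_max − g_min), expanded into a type-2
   footprint of uncertainty with an upper bound μ^α and a lower bound
   μ^(1/α) (0 < α ≤ 1, default α = 0.9), and recombined with the Hamacher
   T co-norm

       S_λ(a, b) = (a + b + (λ − 2)·a·b) / (1 − (1 − λ)·a·b),

   with λ set to the mean of the fuzzified map. The result is defuzzified
   back onto [g_min, g_max]. The union pushes memberships toward 1 wherever
   either bound is high, raising the contrast between lesions and
   background.
2. **A trigonometric activation function** f(x) = x / cos x with the
   closed-form derivative f′(x) = (cos x + x sin x)/cos² x. It satisfies
   f(0) = 0, f′(0) = 1, is odd and strictly increasing on (−π/2, π/2), and
   its derivative never vanishes on that interval — the vanishing-gradient
   regime of sigmoid-like activations does not occur. Training uses a
   clamped variant (pre-activations clipped to a symmetric bound inside the
   pole at π/2).
3. **A small CNN** (32×32 input; four blocks of 3×3 stride-1 convolution →
   activation → 2×2 max-pool; two fully connected layers; softmax) trained
   with categorical cross-entropy and the Nadam optimizer. The activation is
   resolved by name from a registry, so the trigonometric function and the
   standard references (tanh, sigmoid, ReLU, LReLU, ELU, SELU, Swish, Mish)
   are interchangeable without changing shapes or parameter counts.
4. **A sweep harness** that retrains the network over grids of activations ×
   epochs × learning rates × batch sizes and pivots the results into
   activation-by-grid-value accuracy tables.
5. **A synthetic fundus generator** producing seeded, grade-labelled,
   schematic retina images (disc, vessels, grade-dependent lesion counts),
   so the whole pipeline is testable without any dataset download.

Intended users: researchers benchmarking activation functions or
fuzzy-enhancement preprocessing on retinal imagery, and anyone who needs a
small, dependency-light, fully reproducible CNN training loop in NumPy.

## Worked example

```python
import numpy as np
from fundusdr import (FundusSynthConfig, generate_arrays, FundusCNNClassifier,
                      compute_metrics, Type2FuzzyEnhancer,
                      proposed_forward, proposed_derivative)

# the activation and its analytic derivative
print(proposed_forward(1.0))     # 1.8508157176809255  (= 1/cos 1)
print(proposed_derivative(1.0))  # 4.733290413309905   (= (cos1 + sin1)/cos²1)

# 125 synthetic fundus images: 100 train / 25 test, grades 0..4
cfg = FundusSynthConfig(per_grade_n=25, test_fraction=0.2)
train, test = generate_arrays(cfg)

# enhance one image (green channel)
enh = Type2FuzzyEnhancer(alpha=0.9)
out = enh.transform(train[60].image)
print(enh.lambdas_[0])                       # 0.3037  (λ = mean membership)
print(train[60].image[..., 1].std(), out.std())  # 69.08 → 88.12

# train the CNN with the trigonometric activation
clf = FundusCNNClassifier(activation="proposed", random_state=0)
clf.fit([s.image for s in train], np.array([s.grade for s in train]))
print(clf.history_["accuracy"].iloc[-1])     # 1.0  (final training accuracy)

rep = compute_metrics(np.array([s.grade for s in test]),
                      clf.predict_proba([s.image for s in test]))
print(rep.as_dict())
# {'accuracy': 0.84, 'sensitivity': 0.84, 'specificity': 0.96,
#  'precision': 0.86, 'f1': 0.843, 'auc': 0.974, 'loss': 0.375}
```

The enhancement raises the green-channel standard deviation from 69.1 to
88.1 (stronger lesion/background contrast); the classifier fits the 100
training images perfectly within 30 epochs and grades 84 % of the held-out
images correctly, with macro one-vs-rest AUC 0.97.

The same operations are available from a CLI:

```
fundusdr generate --out data --per-grade-n 25
fundusdr enhance  --input data --output enhanced --alpha 0.9 --channel green
fundusdr train    --data data --out run --activation proposed --seed 0
fundusdr sweep    --data data --out sweeprun --pivot lr
```

Every run writes a `run_manifest.json` with the resolved configuration, and
identical command + config + seed reproduce byte-identical CSV outputs.

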