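# dendrilearn

Learning algorithms for dendritic tree networks: backpropagation
specialized to tree connectivity, momentum training with
accumulative-field subtraction, order-3 input-cross feature expansion with
its dendritic-amplification algebra, and least-action perceptron
committees — plus IDX data handling, ensembling, and synthetic fixtures so
everything runs without downloads.

## The problem

The textbook account of learning — synaptic plasticity — places adaptation
at the synapse between two neurons. An alternative places it on dendritic
tree *segments*, each carrying an adjustable weight and a nonlinear
amplification. This package implements the machine-learning side of that
picture for handwritten-digit-style classification:

- **Tree backpropagation (TBP).** On a feedforward tree network (FFTN)
  every weight reaches an output unit through exactly one route, so exact
  backpropagation needs only local state along that route. The
  `fftn_identifier` preset is a bank of ten one-vs-all tree nets (784
  inputs → 49 hidden units with non-overlapping 16-pixel receptive fields
  → 1 output); prediction is the argmax of the ten outputs. Dense
  variants (784–100–100–10, and a one-hidden-layer net with input crosses)
  keep the one-route-per-*weight* property.
- **Momentum training with field subtraction.** Updates follow
  V ← μV − η∇C, W ← (1−α)W + V, b ← b + V_b, with per-output binary
  cross-entropy plus an α/(2η)ΣW² penalty realized exactly by the (1−α)
  decay. Each first-hidden-layer field is reduced by Amp₁ times the
  running average of that unit's past raw fields (never the first
  example).
- **Input crosses.** A nonlinear dendritic segment amplifier A(I) = I + I²
  applied to a sum of inputs generates products of inputs for free. The
  package both expands that algebra symbolically and emulates it by
  appending order-3 crosses X_k·X_l·X_j as extra features — the same fixed
  number per hidden unit, uniqueness and nonzero-on-train enforced, initial
  weights rescaled by √(n_regular/n_crosses) (= 0.28 for 784 and 10,000).
- **Least-action committees.** A Hebbian digit identifier is a committee
  of seven sign perceptrons with unit output weights. An example triggers
  an update only when fewer than 5 members output the desired ±1 label,
  and then only the erring member with the minimal absolute local field
  moves: W ← (1−α)W + η(y−a)X.
- **Soft committees.** Replicas trained from different initial weights are
  ensembled by summing raw outputs before the argmax.

See `docs/methods.md` for the full model account, conventions and
limitations.

## Worked example

```python
import dendrilearn as dl

# synthetic digit-shaped data: 10 classes, 28x28 uint8, 10 constant pixels
spec = dl.SyntheticSpec(noise_std=100, prototype_contrast=20, seed=1)
train, test = dl.gen_images(spec)
norm_train, norm_test = dl.normalize_pair(train, test)
print("masked pixels:", dl.zero_variance_mask(train).sum())

hp = dl.HebbianHyperparams(eta=0.05, alpha=0.0002, epochs=20, seed=1)
model = dl.HebbianCommitteeClassifier(norm_train, hp)
res = model.fit(seed=1)
print(res.summary())
print(f"test error: {res.test_error(norm_test):.3f}")
```

prints

```
masked pixels: 10
Hebbian least-action committee classifier
================================================
identifiers:      10 x 7 perceptrons
eta=0.05  alpha=0.0002  epochs=20
crosses/member:   0
final mean per-identifier train error: 0.0000
test error: 0.068
```

The ten constant pixels planted by the generator are exactly the ones the
zero-variance mask removes; each of the ten identifier committees reaches
zero training error on its ±1 problem, and the argmax over committee
values misclassifies 6.8% of the 500 held-out examples on this low-contrast
synthetic benchmark.

The gradient-trained models follow the same Model → fit() → Results
pattern:

```python
hp = dl.Hyperparams(eta=0.05, mu=0.9, alpha=1e-5, amp1=0.1, epochs=20, seed=1)
res = dl.DendriticNetClassifier(norm_train, "fftn_identifier", hp).fit(seed=1)
err = res.test_error(norm_test)
committee = dl.fit_committee(
    lambda: dl.DendriticNetClassifier(norm_train, "fftn_identifier", hp),
    n_replicas=3, base_seed=17,
)
err_committee = committee.test_error(norm_test)
```

## Command line

```bash
dendrilearn fixtures  --out data/ --seed 0
dendrilearn normalize --train data/train-images.idx --train-labels data/train-labels.idx \
                      --test data/test-images.idx --test-labels data/test-labels.idx --out norm/
dendrilearn crosses   --train-npz norm/train-normalized.npz --n 10000 --units 100 --out crosses.json
dendrilearn train     --arch fftn --train-npz norm/train-normalized.npz --seed 1 --out fftn.pkl
dendrilearn eval      --ckpt fftn.pkl --test-npz norm/test-normalized.npz --out report.json
```

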