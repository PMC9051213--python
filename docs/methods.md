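# Methods

`dendrilearn` implements a family of learning algorithms motivated by the
hypothesis that adaptation in biological neurons happens on dendritic tree
segments — each segment carrying a tunable weight and a nonlinear
amplification — rather than (or in addition to) at individual synapses. The
package contains three trainable architectures, the feature-expansion
machinery that emulates what nonlinear dendritic amplification provides for
free, and the evaluation and data tooling around them.

## Input normalization

Raw examples are uint8 images (pixels in [0, 255]). Each example is
independently centered and scaled: its own pixel mean is subtracted and it
is divided by its own pixel standard deviation. We use the population
convention (divide by P, `ddof=0`) so that the per-example std is exactly 1;
`normalize(..., ddof=1)` switches to the sample convention. Any pixel that
takes a single value across the entire *training* set (a "zero-variance"
pixel, e.g. the constant border of scanned digits) is then set to exactly 0
in both train and test data; the mask is always derived from the training
set alone. Normalization happens first and masking second, so the surviving
pixels keep the mean-0/std-1 statistics of the full example.

A constant example (std 0) cannot occur in real scans; for synthetic inputs
it is emitted as all zeros with a warning rather than an error.

## Architectures and initialization

Three gradient-trained presets are wired in:

- `fftn_identifier` — a one-vs-all tree network per digit: 784 inputs split
  into 49 non-overlapping groups of 16 consecutive row-major pixels, one
  hidden unit per group, one sigmoid output. Connectivity is encoded as a
  boolean mask on the first weight matrix; masked entries are exactly zero
  at initialization and are re-zeroed after every update, so tree structure
  is conserved bit-exactly through training. The bank of 10 identifiers is
  trained fully independently (the total error decomposes as a sum of
  per-identifier errors); prediction is the argmax of the 10 scalar outputs.
- `fully_connected_2h` — 784–100–100–10, dense, 10 sigmoid outputs trained
  with per-output binary cross-entropy on one-hot targets (no softmax).
- `crosses_1h` — 784 inputs plus 10,000 order-3 input crosses per hidden
  unit, one hidden layer of 100, 10 outputs.

Weights are drawn Gaussian(0, 1) and then, per unit, the incoming weights
are shifted and scaled to empirical mean 0 and population std 1
(initialization only; masked entries are excluded from the statistics). All
biases start at 1. For the crosses architecture the cross weights take part
in the per-unit normalization and are afterwards rescaled by
√(n_regular/n_crosses) — exactly 0.28 for (784, 10,000) — which equalizes
the expected contribution of the regular and cross input blocks to the
initial field.

## Forward pass with accumulative-field subtraction

The first hidden layer computes the usual affine field
z¹ = W¹ᵀx + b¹ (plus per-unit cross terms where present) and then subtracts
`Amp1` times the running average of that unit's *raw* fields over all
previously presented training examples; the very first example is never
adjusted. Subsequent layers are plain affine + logistic. Design choices the
update equations leave open, each behind an explicit argument:

- the accumulator collects raw (pre-subtraction) fields — the subtraction
  references the field propagating from the input layer;
- it runs across epochs without reset;
- at test time it is frozen at its end-of-training value and the
  subtraction is still applied, keeping the train and test forward
  functions identical;
- only the first hidden layer is adjusted; deeper layers are plain.

The logistic exponent is clipped at ±500 so saturated units neither
overflow nor produce NaNs; the clip is inert for any reachable field in
practice.

## Cost, gradients and the momentum/decay update

The cost is per-output binary cross-entropy summed over output units and
averaged over examples, plus an L2 term α/(2η)·ΣW² over all weight matrices
(never biases). Outputs are clipped to [1e-12, 1−1e-12] inside the logs.

Backpropagation is exact for the data term: the subtracted running average
is a function of past examples only and is treated as a constant, and tree
masks zero the corresponding gradient entries. The update is

    V ← μV − η∇C_data,  W ← (1−α)W + V,  b ← b + V_b

with velocities initialized at zero, which makes the first applied velocity
exactly −η·(first gradient). For μ = 0 the (1−α) decay factor realizes one
gradient-descent step on the *full* cost — the derivative of α/(2η)ΣW² is
(α/η)W and −η·(α/η)W = −αW — so the decay IS the regularizer; computing
both would double-count it. Biases are neither decayed nor masked. Updates
are per-example by default; `minibatch > 1` averages gradients over each
batch (used by the full-dataset dense preset). Example order is reshuffled
every epoch from the run seed; the field accumulator follows presentation
order. Non-finite cost aborts training with a diagnostic.

## Input crosses and the amplifier algebra

An order-3 input cross is the product X_k·X_l·X_j of three distinct pixels,
appended as an extra input feature. Each hidden unit receives exactly the
same number of crosses (micro-canonical assignment; 10,000 at full scale),
sampled independently per unit. A triple is rejected if its indices repeat,
if it duplicates an earlier triple of the same unit as an unordered set, or
if its product is zero on every training example (which in particular
removes every triple touching a masked pixel). Sampling is exhaustive
enumeration below ~2·10⁵ candidate triples (making the feasibility error
exact) and batched rejection sampling above. Triples are 0-based internally
and serialize to a JSON sidecar for reproducibility.

The algebra that motivates crosses is implemented symbolically:
`expand_amplifier` returns the multinomial expansion of a polynomial segment
amplifier A(ΣIᵢ); for the canonical A(I) = I + I² over k inputs this yields
each Iᵢ (coefficient 1), each Iᵢ² (1), and each pairwise cross IᵢIⱼ
(coefficient 2) — k + k + C(k,2) monomials. `synapse_equivalence` shifts a
*linear* segment gain g·I onto the segment's incoming synaptic (and carry)
weights, producing an output-identical chain; a nonlinear amplifier has no
such synaptic equivalent, which is precisely why nonlinear dendritic
amplification adds representational power, and the function raises on it.
`count_crosses(n, r) = C(n, r)` quantifies the combinatorial budget (about
5·10⁵ order-2 crosses already at a thousand inputs).

## Least-action committees

A Hebbian identifier is a committee of seven sign perceptrons over the
(cross-expanded) input with output weights fixed at one and no bias; member
outputs are ±1 with a strict threshold (z = 0 → −1) and the committee value
is their sum. On each presented example all seven fields are read
synchronously; if at least 5 members already output the desired ±1 label,
nothing changes. Otherwise exactly one perceptron — the erring one with the
minimal |z|, ties to the lowest index — receives

    W ← (1−α)W + η(y − a)X,   a ∈ {−1, +1}, so η(y−a) = ±2η,

decay included only for that member on that step. With α = 0 the update
moves the member's field on the triggering example by exactly 2η‖x‖²
toward the label. Defaults η = 0.05, α = 0.0002. The gate and committee
size are parameters; a committee of one with gate one reduces to the
classical perceptron rule with decay. Cross sets are per-member (seven
independent sets per identifier), and the √(n_regular/n_crosses) rescale is
applied to initial cross weights for scale consistency (flag
`rescale_crosses` to disable — no rescale is printed for this architecture,
we apply it as the package's own choice). The ten identifiers consume RNG
streams derived from (seed, digit), so they are independent of training
order.

## Ensembles and evaluation

A soft committee sums the raw output-unit values of Nc replicas trained
from different initial weights and takes the argmax; Nc = 1 reduces to the
single-net argmax, and for identifier banks the per-identifier sums are
taken before the across-identifier argmax. `test_error` is the plain
misclassification fraction; spreads across seeds are sample standard
deviations (ddof = 1). Argmax ties resolve to the lowest label index; the
Hebbian predictor breaks committee-value ties by the larger summed field
first.

## Synthetic data

`gen_images` emulates the statistics the algorithms assume: 28×28 uint8
images, class structure, and a block of pixels constant across the training
set to exercise zero-variance masking. Each class gets a smooth prototype
(Gaussian-filtered white noise, σ = 2.5, scaled to a chosen contrast around
mid-gray); examples are the prototype plus iid pixel noise, clipped and
quantized. A guard nudges any *accidentally* constant pixel so the
zero-variance mask marks exactly the designated ones. What this emulates —
and what it does not: class-conditional structure, pixel quantization,
constant borders, yes; the within-class deformation diversity of real
handwriting, no. Synthetic learning curves are therefore much steeper than
real ones (class manifolds are points + noise, so error collapses quickly
once per-class sample means stabilize), and passing desk-scale tests
demonstrates correctness of the machinery, not real-data accuracy.

Defaults: 10 classes × 100 train + 50 test, contrast 70, noise 25, ten
constant pixels — comfortably separable, which is what unit tests want.
The acceptance benchmark (below) deliberately uses contrast 20 / noise 100,
a low-SNR condition chosen once so that desk-scale test errors sit
measurably between zero and chance and the power-law fit has positive
errors to work with.

`gen_teacher_labels` labels inputs by majority vote of a random 7-member
sign committee (odd size: no ties) — a realizable target for the
least-action learner. `gen_separable` produces two unit-variance Gaussian
clouds with centers 2·margin apart for gradient-trainer sanity checks. All
generators are pure functions of their spec and seed.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run at desk scale as the
package's own choice of problem size: fixture datasets of 300–1,000
examples, tree nets at 64–784 inputs, cross sets of 100 per unit (the
full 10,000-count contract is checked on one unit), committees of 3, and
20–30 training epochs. The full-scale configurations from the original
study (50,000 examples, 200–300 epochs, 10,000 crosses per unit on all 100
units) are wired in as presets (`presets.py`) and documented in the README
as a reproduction recipe requiring the external handwritten-digit corpus.

Numerical conventions collected in one place: population std everywhere a
std is "set to 1"; logistic exponent clip ±500; cross-entropy clip 1e-12;
√(n_reg)/√(n_cross) computed as a quotient of square roots so perfect
squares give exact factors; gradient checks compare central differences
(h = 1e-6) against analytic gradients relative to each array's gradient
infinity norm (elementwise ratios on near-zero entries measure FD roundoff,
not the gradient); argmax ties to the lowest index; checkpoint round trips
preserve float64 bit patterns.

## Known limitations

- The running-average subtraction makes training order-dependent; only the
  seeded shuffle is reproducible, not any claim of order-invariance.
- Training loops are per-example Python loops over numpy ops — fine at desk
  scale and for the full-scale presets given hours, not optimized beyond
  that.
- The committee/identifier machinery assumes 10 classes by default but is
  parametric; only the three printed architectures are presets.
- The 10 identifier updates per shared input that a biological realization
  would perform asynchronously are executed synchronously here.
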