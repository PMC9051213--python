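"""Order-3 input crosses and the dendritic-amplification cross algebra.

An input cross is a product of raw input values, X_{k,l,j} = X_k * X_l * X_j,
appended to the network input as an extra feature. Crosses emulate the
higher-order interaction terms that a nonlinear dendritic segment amplifier
(e.g. A(I) = I + I^2 applied to a sum of synaptic inputs) generates for free.
Each hidden unit receives the same fixed number of crosses (micro-canonical
assignment), sampled independently per unit.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Below this many candidate triples we enumerate exhaustively instead of
# rejection-sampling, which makes the feasibility error exact.
_EXHAUSTIVE_LIMIT = 200_000


@dataclass
class CrossIndexSet:
    """Per-hidden-unit lists of order-3 input index triples (0-based).

    Each unit's triples are unique as unordered sets, have three distinct
    indices, and none has a product that is identically zero on the
    training set.
    """

    per_unit: list  # list of (n_crosses, 3) int64 arrays, rows sorted ascending
    n_regular_inputs: int

    def __post_init__(self) -> None:
        self.per_unit = [np.asarray(t, dtype=np.int64).reshape(-1, 3) for t in self.per_unit]

    @property
    def n_units(self) -> int:
        return len(self.per_unit)

    @property
    def n_crosses(self) -> int:
        return int(self.per_unit[0].shape[0]) if self.per_unit else 0

    def stacked(self) -> np.ndarray:
        """(n_units, n_crosses, 3) index tensor for vectorized evaluation."""
        return np.stack(self.per_unit, axis=0)

    def to_json(self, path) -> Path:
        payload = {
            "n_regular_inputs": self.n_regular_inputs,
            "per_unit": [t.tolist() for t in self.per_unit],
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path) -> "CrossIndexSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            per_unit=[np.asarray(t, dtype=np.int64) for t in payload["per_unit"]],
            n_regular_inputs=int(payload["n_regular_inputs"]),
        )


def _dead_triples(zero_mask: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """True where the triple's product is zero on EVERY training example.

    zero_mask is the (M, P) boolean matrix of exact zeros in the training
    inputs; a triple is dead iff every example has a zero among its three
    pixels.
    """
    z = zero_mask[:, triples[:, 0]] | zero_mask[:, triples[:, 1]] | zero_mask[:, triples[:, 2]]
    return z.all(axis=0)


def _valid_candidates(zero_mask: np.ndarray, cand: np.ndarray) -> np.ndarray:
    cand = np.sort(cand, axis=1)
    distinct = (cand[:, 0] != cand[:, 1]) & (cand[:, 1] != cand[:, 2])
    cand = cand[distinct]
    if cand.size:
        cand = cand[~_dead_triples(zero_mask, cand)]
    return cand


def _sample_unit(
    rng: np.random.Generator, n_inputs: int, n_crosses: int, zero_mask: np.ndarray
) -> np.ndarray:
    total = math.comb(n_inputs, 3)
    if total <= _EXHAUSTIVE_LIMIT:
        all_triples = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n_inputs), 3)),
            dtype=np.int64,
        ).reshape(-1, 3)
        valid = all_triples[~_dead_triples(zero_mask, all_triples)]
        if valid.shape[0] < n_crosses:
            raise ValueError(
                f"requested {n_crosses} crosses per unit but only "
                f"{valid.shape[0]} valid triples exist"
            )
        pick = rng.choice(valid.shape[0], size=n_crosses, replace=False)
        return valid[np.sort(pick)]

    chosen: set[tuple[int, int, int]] = set()
    rows: list[np.ndarray] = []
    stalls = 0
    while len(chosen) < n_crosses:
        batch = max(4 * (n_crosses - len(chosen)), 4096)
        cand = _valid_candidates(
            zero_mask, rng.integers(0, n_inputs, size=(batch, 3), dtype=np.int64)
        )
        added = 0
        for row in cand:
            key = (int(row[0]), int(row[1]), int(row[2]))
            if key not in chosen:
                chosen.add(key)
                rows.append(row)
                added += 1
                if len(chosen) == n_crosses:
                    break
        stalls = stalls + 1 if added == 0 else 0
        if stalls >= 50:  # pragma: no cover - unreachable at realistic sizes
            raise ValueError(
                f"could not collect {n_crosses} valid crosses; "
                f"{len(chosen)} found after repeated resampling"
            )
    return np.asarray(rows, dtype=np.int64)


def generate_crosses(
    n_inputs: int,
    n_crosses: int,
    n_hidden: int,
    train_inputs: np.ndarray,
    seed: int,
    *,
    share_across_units: bool = False,
) -> CrossIndexSet:
    """Sample order-3 index triples for each hidden unit.

    Every unit receives exactly ``n_crosses`` triples (micro-canonical
    assignment). Triples are unique per unit as unordered sets, use three
    distinct indices, and any triple whose product is zero on every training
    example (e.g. one involving a zero-variance-masked pixel) is excluded
    and resampled. ``train_inputs`` are the normalized, masked values that
    the network actually sees.

    With ``share_across_units`` one set is sampled and shared by all units.
    """
    if n_inputs < 3:
        raise ValueError("need at least 3 inputs to form a triple")
    train_inputs = np.atleast_2d(np.asarray(train_inputs, dtype=np.float64))
    if train_inputs.shape[1] != n_inputs:
        raise ValueError("train_inputs width does not match n_inputs")
    if train_inputs.shape[0] < 1:
        raise ValueError("training set must be nonempty")
    zero_mask = train_inputs == 0.0
    seeds = np.random.SeedSequence(seed).spawn(1 if share_across_units else n_hidden)
    if share_across_units:
        one = _sample_unit(np.random.default_rng(seeds[0]), n_inputs, n_crosses, zero_mask)
        per_unit = [one.copy() for _ in range(n_hidden)]
    else:
        per_unit = [
            _sample_unit(np.random.default_rng(s), n_inputs, n_crosses, zero_mask)
            for s in seeds
        ]
    return CrossIndexSet(per_unit=per_unit, n_regular_inputs=n_inputs)


def cross_inputs(x: np.ndarray, crosses: CrossIndexSet, unit: int) -> np.ndarray:
    """Cross features of one example for one hidden unit: element t is the
    product of the three pixels indexed by triple t."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != crosses.n_regular_inputs:
        raise ValueError("input length does not match the cross set")
    t = crosses.per_unit[unit]
    return x[..., t[:, 0]] * x[..., t[:, 1]] * x[..., t[:, 2]]


def cross_inputs_all_units(x: np.ndarray, crosses: CrossIndexSet) -> np.ndarray:
    """(n_units, n_crosses) cross features of one example for every unit."""
    x = np.asarray(x, dtype=np.float64)
    t = crosses.stacked()
    return x[t[..., 0]] * x[t[..., 1]] * x[t[..., 2]]


def rescale_cross_weights(w: np.ndarray, n_regular: int, n_crosses: int) -> np.ndarray:
    """Scale initial cross weights by sqrt(n_regular / n_crosses).

    With 784 regular inputs and 10,000 crosses the factor is exactly 0.28.
    Applied once, after the per-unit initial weight normalization.
    """
    if n_crosses <= 0:
        raise ValueError("n_crosses must be positive")
    # sqrt of numerator and denominator separately: exact for perfect squares
    # (sqrt(784)/sqrt(10000) = 28/100 = 0.28 to the last bit)
    factor = math.sqrt(n_regular) / math.sqrt(n_crosses)
    return np.asarray(w, dtype=np.float64) * factor


def count_crosses(n_inputs: int, order: int) -> int:
    """Number of distinct unordered input crosses: C(n_inputs, order)."""
    if not 0 < order <= n_inputs:
        raise ValueError("order must satisfy 0 < order <= n_inputs")
    return math.comb(n_inputs, order)


# ---------------------------------------------------------------------------
# Amplifier algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplifierSpec:
    """Polynomial segment amplifier A(I) = sum_r c_r I^r with A(0) = 0.

    ``coefficients`` lists c_1..c_d (no constant term). The canonical
    nonlinear example is A(I) = I + I^2, i.e. coefficients (1, 1); a linear
    amplifier g*I has coefficients (g,).
    """

    coefficients: tuple

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) < 1:
            raise ValueError("amplifier needs degree >= 1")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def degree(self) -> int:
        return len(self.coefficients)

    @property
    def is_linear(self) -> bool:
        return all(c == 0.0 for c in self.coefficients[1:])

    @property
    def gain(self) -> float:
        return self.coefficients[0]

    def __call__(self, value):
        value = np.asarray(value, dtype=np.float64)
        out = np.zeros_like(value)
        for c in reversed(self.coefficients):
            out = value * (out + c)
        return out if out.ndim else float(out)


IDENTITY_AMPLIFIER = AmplifierSpec((1.0,))


def expand_amplifier(amp: AmplifierSpec, k: int) -> dict:
    """Multinomial expansion of A(I_1 + ... + I_k).

    Returns a map from exponent tuples (e_1..e_k) to coefficients. For
    A(I) = I + I^2 and any k this yields each I_i with coefficient 1
    (linear term), each I_i^2 with coefficient 1, and each pairwise cross
    I_i*I_j (i < j) with coefficient 2 — the mechanism by which one
    quadratic dendritic segment generates input crosses.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    monomials: dict[tuple, float] = {}
    for r, c in enumerate(amp.coefficients, start=1):
        if c == 0.0:
            continue
        for exponents in _compositions(r, k):
            coeff = c * _multinomial(r, exponents)
            key = tuple(exponents)
            monomials[key] = monomials.get(key, 0.0) + coeff
    return monomials


def _compositions(total: int, parts: int):
    """All tuples of `parts` nonnegative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head,) + rest


def _multinomial(r: int, exponents) -> float:
    denom = 1
    for e in exponents:
        denom *= math.factorial(e)
    return math.factorial(r) / denom


def evaluate_expansion(monomials: dict, values: np.ndarray) -> float:
    """Evaluate a monomial->coefficient map at a vector of input values."""
    values = np.asarray(values, dtype=np.float64)
    total = 0.0
    for exponents, coeff in monomials.items():
        total += coeff * np.prod(values ** np.asarray(exponents))
    return float(total)


# ---------------------------------------------------------------------------
# Segment chains and the segment<->synapse equivalence
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One dendritic segment: synaptic weights over its own input group, a
    carry weight on the upstream segment's output, an amplifier, and the
    segment weight applied to the amplified signal."""

    synaptic_weights: np.ndarray
    amplifier: AmplifierSpec = IDENTITY_AMPLIFIER
    weight: float = 1.0
    carry_weight: float = 1.0

    def __post_init__(self) -> None:
        self.synaptic_weights = np.asarray(self.synaptic_weights, dtype=np.float64)


@dataclass
class SegmentChain:
    """An acyclic chain of segments toward a single output (the soma).

    ``input_groups[i]`` gives the input indices feeding segment i; the
    chain output is W_d * A_d(I_d) where
    I_i = carry_i * output_{i-1} + w_i . x[group_i].
    """

    segments: list
    input_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.input_groups:
            offset = 0
            self.input_groups = []
            for seg in self.segments:
                n = seg.synaptic_weights.shape[0]
                self.input_groups.append(np.arange(offset, offset + n))
                offset += n
        self.input_groups = [np.asarray(g, dtype=np.int64) for g in self.input_groups]

    @property
    def n_inputs(self) -> int:
        return int(max(g.max() for g in self.input_groups)) + 1

    def evaluate(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=np.float64)
        signal = 0.0
        for seg, group in zip(self.segments, self.input_groups):
            influx = seg.carry_weight * signal + float(seg.synaptic_weights @ x[group])
            signal = seg.weight * seg.amplifier(influx)
        return float(signal)


def synapse_equivalence(chain: SegmentChain, segment_index: int = 0) -> SegmentChain:
    """Shift a linear segment amplification g*I onto its synapses.

    The segment's synaptic weights (and carry weight) are multiplied by g and
    its amplifier replaced by the identity; the two chains produce identical
    outputs on every input. Only linear amplification admits this
    equivalence — a nonlinear amplifier raises an error.
    """
    seg = chain.segments[segment_index]
    if not seg.amplifier.is_linear:
        raise ValueError("segment<->synapse equivalence holds only for linear amplification")
    g = seg.amplifier.gain
    new_seg = Segment(
        synaptic_weights=seg.synaptic_weights * g,
        amplifier=IDENTITY_AMPLIFIER,
        weight=seg.weight,
        carry_weight=seg.carry_weight * g,
    )
    segments = list(chain.segments)
    segments[segment_index] = new_seg
    return SegmentChain(
        segments=segments, input_groups=[grp.copy() for grp in chain.input_groups]
    )
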