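"""Network containers, initialization, connectivity masks and the forward pass.

The forward pass is the standard affine + logistic composition with one
twist on the first hidden layer: each unit's field is reduced by
``Amp1`` times the running average of that unit's raw fields over all
previously presented examples (no reduction for the very first example).
The running average is over RAW, pre-subtraction fields and is treated as a
constant during backpropagation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crosses import CrossIndexSet, cross_inputs_all_units, rescale_cross_weights

ARCHITECTURES = ("fftn_identifier", "fully_connected_2h", "crosses_1h")


@dataclass
class Hyperparams:
    """Training constants.

    eta   : learning rate (> 0)
    mu    : momentum constant in [0, 1)
    alpha : weight-decay constant in [0, 1); realizes the L2 cost term
            alpha/(2*eta) * sum W^2 exactly (see trainer notes)
    amp1  : amplitude of the accumulative-average field reduction (>= 0)
    """

    eta: float = 0.01
    mu: float = 0.0
    alpha: float = 0.0
    amp1: float = 0.0
    epochs: int = 1
    minibatch: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.amp1 < 0:
            raise ValueError("amp1 must be nonnegative")
        if self.epochs < 1 or self.minibatch < 1:
            raise ValueError("epochs and minibatch must be >= 1")


@dataclass
class LayerWeights:
    """Weights of one layer: W is (fan_in, fan_out), b is (fan_out,)."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)

    def copy(self) -> "LayerWeights":
        return LayerWeights(self.W.copy(), self.b.copy())


def block_receptive_field_mask(n_inputs: int, block: int) -> np.ndarray:
    """Tree connectivity: hidden unit j owns the `block` consecutive
    row-major pixels block*j .. block*(j+1)-1; blocks are non-overlapping
    and tile the input (784 = 49 x 16 in the digit-identifier layout)."""
    if n_inputs % block != 0:
        raise ValueError("block size must divide the number of inputs")
    n_hidden = n_inputs // block
    mask = np.zeros((n_inputs, n_hidden), dtype=bool)
    for j in range(n_hidden):
        mask[block * j : block * (j + 1), j] = True
    return mask


@dataclass
class RunningFieldState:
    """Accumulator for the first-hidden-layer raw fields.

    sum_z : per-unit sum of raw fields over the m examples seen so far
    m     : number of training examples presented since initialization
    """

    sum_z: np.ndarray
    m: int = 0

    def __post_init__(self) -> None:
        self.sum_z = np.asarray(self.sum_z, dtype=np.float64)

    def copy(self) -> "RunningFieldState":
        return RunningFieldState(self.sum_z.copy(), self.m)

    def reset(self) -> None:
        self.sum_z[:] = 0.0
        self.m = 0


@dataclass
class NetworkParams:
    """Layer weights plus optional tree mask and per-unit cross weights.

    ``masks[l]``, when present, marks the allowed entries of layers[l].W;
    masked-out entries are exactly 0 and stay 0 through training.
    ``cross_weights`` is (n_crosses, n_hidden) — column j holds hidden unit
    j's weights onto its own cross features.
    """

    layers: list
    masks: list = field(default_factory=list)
    cross_weights: np.ndarray | None = None
    architecture: str = "custom"

    def __post_init__(self) -> None:
        if not self.masks:
            self.masks = [None] * len(self.layers)
        if len(self.masks) != len(self.layers):
            raise ValueError("one (possibly None) mask per layer required")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def layer_sizes(self) -> list:
        return [self.layers[0].W.shape[0]] + [lw.W.shape[1] for lw in self.layers]

    @property
    def n_hidden_first(self) -> int:
        return self.layers[0].W.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            layers=[lw.copy() for lw in self.layers],
            masks=[None if m is None else m.copy() for m in self.masks],
            cross_weights=None if self.cross_weights is None else self.cross_weights.copy(),
            architecture=self.architecture,
        )

    def new_field_state(self) -> RunningFieldState:
        return RunningFieldState(np.zeros(self.n_hidden_first))

    def apply_masks(self) -> None:
        for lw, m in zip(self.layers, self.masks):
            if m is not None:
                lw.W[~m] = 0.0


def sigmoid(z):
    """Logistic activation 1/(1+e^{-z}); exponent clipped so large |z|
    saturates without overflow."""
    z = np.clip(np.asarray(z, dtype=np.float64), -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


def _normalize_columns(W: np.ndarray, mask: np.ndarray | None) -> None:
    """Shift/scale each unit's incoming (unmasked) weights to empirical
    mean 0, population std 1. Initialization only."""
    for j in range(W.shape[1]):
        col = W[:, j] if mask is None else W[mask[:, j], j]
        if col.size < 2:
            continue
        mu, sd = col.mean(), col.std()
        if sd == 0.0:  # pragma: no cover - measure-zero with Gaussian draws
            continue
        col = (col - mu) / sd
        if mask is None:
            W[:, j] = col
        else:
            W[mask[:, j], j] = col


def init_network(
    layer_sizes,
    seed: int,
    *,
    masks=None,
    crosses: CrossIndexSet | None = None,
    rescale_crosses: bool = True,
    architecture: str = "custom",
) -> NetworkParams:
    """Gaussian(0,1) weights; per-unit incoming weights re-normalized to
    empirical mean 0 / std 1 (initialization only); all biases set to 1.

    When ``crosses`` is given, each first-layer unit additionally receives
    weights onto its n_crosses cross features; those take part in the
    per-unit normalization and are then rescaled by
    sqrt(n_regular / n_crosses).
    """
    rng = np.random.default_rng(seed)
    masks = list(masks) if masks is not None else [None] * (len(layer_sizes) - 1)
    layers = []
    cross_weights = None
    for l, (fan_in, fan_out) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        W = rng.standard_normal((fan_in, fan_out))
        m = masks[l]
        if m is not None:
            W[~m] = 0.0
        if l == 0 and crosses is not None:
            if crosses.n_units != fan_out:
                raise ValueError("cross set does not match the first hidden layer width")
            Wc = rng.standard_normal((crosses.n_crosses, fan_out))
            if m is None:
                joint = np.vstack([W, Wc])
                _normalize_columns(joint, None)
                W, Wc = joint[:fan_in], joint[fan_in:]
            else:  # pragma: no cover - crosses with masked layer unused by presets
                joint = np.vstack([W, Wc])
                jm = np.vstack([m, np.ones_like(Wc, dtype=bool)])
                _normalize_columns(joint, jm)
                W, Wc = joint[:fan_in], joint[fan_in:]
            if rescale_crosses:
                Wc = rescale_cross_weights(Wc, fan_in, crosses.n_crosses)
            cross_weights = Wc
        else:
            _normalize_columns(W, m)
        layers.append(LayerWeights(W=W, b=np.ones(fan_out)))
    return NetworkParams(
        layers=layers, masks=masks, cross_weights=cross_weights, architecture=architecture
    )


def init_params(
    architecture: str,
    seed: int,
    *,
    n_inputs: int = 784,
    n_hidden: int | None = None,
    n_outputs: int | None = None,
    block: int = 16,
    crosses: CrossIndexSet | None = None,
    rescale_crosses: bool = True,
) -> NetworkParams:
    """Build one of the preset architectures.

    fftn_identifier    : one-vs-all tree net, n_inputs -> (n_inputs/block)
                         hidden units with non-overlapping consecutive
                         receptive fields -> 1 output (default 784-49-1,
                         block 16).
    fully_connected_2h : n_inputs -> 100 -> 100 -> 10, dense.
    crosses_1h         : n_inputs (+ per-unit crosses) -> 100 -> 10, dense;
                         requires a CrossIndexSet.
    """
    if architecture == "fftn_identifier":
        mask = block_receptive_field_mask(n_inputs, block)
        nh = mask.shape[1]
        return init_network(
            [n_inputs, nh, n_outputs or 1],
            seed,
            masks=[mask, None],
            architecture=architecture,
        )
    if architecture == "fully_connected_2h":
        nh = n_hidden or 100
        return init_network(
            [n_inputs, nh, nh, n_outputs or 10], seed, architecture=architecture
        )
    if architecture == "crosses_1h":
        if crosses is None:
            raise ValueError("crosses_1h requires a CrossIndexSet")
        nh = n_hidden or 100
        return init_network(
            [n_inputs, nh, n_outputs or 10],
            seed,
            crosses=crosses,
            rescale_crosses=rescale_crosses,
            architecture=architecture,
        )
    raise ValueError(f"unknown architecture {architecture!r}; choose from {ARCHITECTURES}")


@dataclass
class ForwardPass:
    """Cached quantities of one forward evaluation."""

    activations: list  # a^1 .. a^L
    raw_first_field: np.ndarray  # z^1 before the Amp1 reduction
    adjusted_first_field: np.ndarray
    cross_features: np.ndarray | None = None  # (n_crosses, n_hidden) or None

    @property
    def output(self) -> np.ndarray:
        return self.activations[-1]


def forward(
    params: NetworkParams,
    x: np.ndarray,
    state: RunningFieldState | None = None,
    amp1: float = 0.0,
    *,
    training: bool = False,
    crosses: CrossIndexSet | None = None,
) -> ForwardPass:
    """One example through the network.

    First hidden layer: z = W.T x (+ per-unit cross terms) + b, then
    z <- z - amp1 * mean(previous raw fields); the first example (m = 1) is
    never adjusted. With ``training=True`` the state accumulates the current
    RAW field in place and increments its counter; with ``training=False``
    the state is read-only (frozen at its end-of-training value at test
    time).
    """
    x = np.asarray(x, dtype=np.float64)
    lw0 = params.layers[0]
    if x.shape[0] != lw0.W.shape[0]:
        raise ValueError(
            f"input length {x.shape[0]} does not match fan-in {lw0.W.shape[0]}"
        )
    z = lw0.W.T @ x + lw0.b
    cross_feats = None
    if params.cross_weights is not None:
        if crosses is None:
            raise ValueError("network has cross weights but no CrossIndexSet was given")
        cross_feats = cross_inputs_all_units(x, crosses).T  # (n_crosses, n_hidden)
        z = z + np.einsum("ch,ch->h", params.cross_weights, cross_feats)
    raw = z.copy()
    if state is not None and amp1 != 0.0 and state.m >= 1:
        z = z - amp1 * state.sum_z / state.m
    if training:
        if state is None:
            raise ValueError("training=True requires a RunningFieldState")
        state.sum_z += raw
        state.m += 1
    activations = [sigmoid(z)]
    for lw in params.layers[1:]:
        activations.append(sigmoid(lw.W.T @ activations[-1] + lw.b))
    return ForwardPass(
        activations=activations,
        raw_first_field=raw,
        adjusted_first_field=z,
        cross_features=cross_feats,
    )


def forward_outputs(
    params: NetworkParams,
    inputs: np.ndarray,
    state: RunningFieldState | None = None,
    amp1: float = 0.0,
    *,
    crosses: CrossIndexSet | None = None,
) -> np.ndarray:
    """Outputs for a batch of examples with a frozen field state."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    return np.stack(
        [forward(params, x, state, amp1, crosses=crosses).output for x in inputs]
    )


# ---------------------------------------------------------------------------
# Checkpoints: npz arrays + JSON manifest; reload reproduces forward output
# bit-exactly (float64 round trip).
# ---------------------------------------------------------------------------


def save_checkpoint(
    path,
    params: NetworkParams,
    state: RunningFieldState | None = None,
    hp: Hyperparams | None = None,
) -> Path:
    path = Path(path)
    arrays = {}
    for i, lw in enumerate(params.layers):
        arrays[f"W{i}"] = lw.W
        arrays[f"b{i}"] = lw.b
        if params.masks[i] is not None:
            arrays[f"mask{i}"] = params.masks[i]
    if params.cross_weights is not None:
        arrays["cross_weights"] = params.cross_weights
    if state is not None:
        arrays["field_sum"] = state.sum_z
    manifest = {
        "architecture": params.architecture,
        "n_layers": params.n_layers,
        "layer_sizes": params.layer_sizes,
        "field_m": None if state is None else state.m,
        "hyperparams": None if hp is None else vars(hp).copy(),
    }
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return path


def load_checkpoint(path):
    """Returns (params, state-or-None, hyperparams-or-None)."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        layers, masks = [], []
        for i in range(manifest["n_layers"]):
            layers.append(LayerWeights(W=data[f"W{i}"], b=data[f"b{i}"]))
            masks.append(data[f"mask{i}"] if f"mask{i}" in data else None)
        cross_weights = data["cross_weights"] if "cross_weights" in data else None
        params = NetworkParams(
            layers=layers,
            masks=masks,
            cross_weights=cross_weights,
            architecture=manifest["architecture"],
        )
        state = None
        if manifest["field_m"] is not None:
            state = RunningFieldState(sum_z=data["field_sum"], m=manifest["field_m"])
    hp = None
    if manifest["hyperparams"] is not None:
        hp = Hyperparams(**manifest["hyperparams"])
    return params, state, hp
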