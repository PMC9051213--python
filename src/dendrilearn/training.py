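"""Cross-entropy cost, exact backpropagation, momentum updates and the
training loop for the gradient-trained architectures.

Regularization note: the update W <- (1-alpha) W + V with V = mu V - eta gC
(gC the gradient of the DATA term only) is exactly one gradient step on the
full cost C = data + alpha/(2 eta) sum W^2 when mu = 0, since
-eta * d/dW [alpha/(2 eta) W^2] = -alpha W. The decay factor therefore IS
the L2 term; computing both would double-count it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crosses import CrossIndexSet
from .network import (
    ForwardPass,
    Hyperparams,
    NetworkParams,
    RunningFieldState,
    forward,
)

CLIP = 1e-12  # outputs clipped to [CLIP, 1-CLIP] inside the log


class TrainingDiverged(RuntimeError):
    """Raised when the cost becomes non-finite."""


@dataclass
class CostReport:
    data_term: float
    l2_term: float

    @property
    def total(self) -> float:
        return self.data_term + self.l2_term


def _weight_square_sum(params: NetworkParams) -> float:
    s = sum(float((lw.W**2).sum()) for lw in params.layers)
    if params.cross_weights is not None:
        s += float((params.cross_weights**2).sum())
    return s


def cost(
    params: NetworkParams,
    outputs: np.ndarray,
    targets: np.ndarray,
    hp: Hyperparams,
) -> CostReport:
    """Binary cross-entropy summed over output units, averaged over the
    batch, plus the L2 term alpha/(2 eta) * sum W^2 over all weight matrices
    (biases excluded). Outputs are clipped to [1e-12, 1-1e-12]."""
    a = np.clip(np.atleast_2d(np.asarray(outputs, dtype=np.float64)), CLIP, 1 - CLIP)
    y = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if a.shape != y.shape:
        raise ValueError("outputs and targets must have the same shape")
    data = float(-(y * np.log(a) + (1 - y) * np.log(1 - a)).sum(axis=1).mean())
    l2 = hp.alpha / (2 * hp.eta) * _weight_square_sum(params) if hp.alpha else 0.0
    return CostReport(data_term=data, l2_term=l2)


@dataclass
class Gradients:
    dW: list
    db: list
    dW_cross: np.ndarray | None = None

    def __iadd__(self, other: "Gradients") -> "Gradients":
        for a, b in zip(self.dW, other.dW):
            a += b
        for a, b in zip(self.db, other.db):
            a += b
        if self.dW_cross is not None:
            self.dW_cross += other.dW_cross
        return self

    def scale(self, factor: float) -> None:
        for a in self.dW:
            a *= factor
        for a in self.db:
            a *= factor
        if self.dW_cross is not None:
            self.dW_cross *= factor


def gradients(
    params: NetworkParams,
    x: np.ndarray,
    targets: np.ndarray,
    fp: ForwardPass,
) -> Gradients:
    """Exact gradients of the cross-entropy DATA term for one example.

    The subtracted accumulative-average field is a function of past examples
    only and is treated as a constant, so the chain rule through the first
    layer is the standard sigmoid backprop. Tree masks zero the
    corresponding gradient entries.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64).ravel()
    acts = fp.activations
    # sigmoid + binary cross-entropy: delta at the output is a - y
    delta = acts[-1] - y
    dW: list = [None] * params.n_layers
    db: list = [None] * params.n_layers
    for l in range(params.n_layers - 1, 0, -1):
        a_prev = acts[l - 1]
        dW[l] = np.outer(a_prev, delta)
        db[l] = delta
        delta = (params.layers[l].W @ delta) * a_prev * (1 - a_prev)
    dW[0] = np.outer(x, delta)
    db[0] = delta
    if params.masks[0] is not None:
        dW[0][~params.masks[0]] = 0.0
    dW_cross = None
    if params.cross_weights is not None:
        if fp.cross_features is None:
            raise ValueError("forward pass lacks cross features")
        dW_cross = fp.cross_features * delta[np.newaxis, :]
    return Gradients(dW=dW, db=db, dW_cross=dW_cross)


@dataclass
class MomentumState:
    """Velocities for every weight matrix and bias vector.

    Zero initialization makes the first applied velocity exactly
    -eta * (first gradient), the stated V0 rule."""

    V: list
    V_b: list
    V_cross: np.ndarray | None = None
    t: int = 0

    @classmethod
    def for_params(cls, params: NetworkParams) -> "MomentumState":
        return cls(
            V=[np.zeros_like(lw.W) for lw in params.layers],
            V_b=[np.zeros_like(lw.b) for lw in params.layers],
            V_cross=(
                None
                if params.cross_weights is None
                else np.zeros_like(params.cross_weights)
            ),
        )

    @property
    def initialized(self) -> bool:
        return self.t > 0


def momentum_step(
    params: NetworkParams,
    grads: Gradients,
    mstate: MomentumState,
    hp: Hyperparams,
) -> None:
    """In-place momentum + decay update.

    V <- mu V - eta gC ; W <- (1-alpha) W + V ; b <- b + V_b (biases are
    neither decayed nor masked). Masks are re-applied after the update.
    """
    for l, lw in enumerate(params.layers):
        mstate.V[l] = hp.mu * mstate.V[l] - hp.eta * grads.dW[l]
        lw.W *= 1 - hp.alpha
        lw.W += mstate.V[l]
        if params.masks[l] is not None:
            lw.W[~params.masks[l]] = 0.0
        mstate.V_b[l] = hp.mu * mstate.V_b[l] - hp.eta * grads.db[l]
        lw.b += mstate.V_b[l]
    if params.cross_weights is not None:
        mstate.V_cross = hp.mu * mstate.V_cross - hp.eta * grads.dW_cross
        params.cross_weights *= 1 - hp.alpha
        params.cross_weights += mstate.V_cross
    mstate.t += 1


@dataclass
class EpochRecord:
    epoch: int
    data_cost: float
    l2_cost: float
    train_accuracy: float


def _predictions_match(outputs: np.ndarray, y: np.ndarray) -> bool:
    if y.size == 1:
        return (outputs.ravel()[0] > 0.5) == (y.ravel()[0] > 0.5)
    return int(np.argmax(outputs)) == int(np.argmax(y))


def train(
    params: NetworkParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    hp: Hyperparams,
    *,
    crosses: CrossIndexSet | None = None,
    state: RunningFieldState | None = None,
    callbacks=None,
) -> tuple[NetworkParams, RunningFieldState, list]:
    """Train in place for hp.epochs passes; returns (params, state, history).

    Targets are one-hot rows for multi-output networks or scalar 0/1 for a
    single-output identifier. Example order is reshuffled every epoch from
    hp.seed; the field accumulator follows presentation order and runs
    across epochs without reset. Updates are per-example by default;
    minibatch > 1 averages gradients over each batch.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim == 1:
        targets = targets[:, np.newaxis]
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError("inputs and targets disagree on the number of examples")
    if state is None:
        state = params.new_field_state()
    mstate = MomentumState.for_params(params)
    order_rng = np.random.default_rng(hp.seed)
    history: list = []
    n = inputs.shape[0]
    for epoch in range(1, hp.epochs + 1):
        order = order_rng.permutation(n)
        epoch_cost = 0.0
        correct = 0
        for start in range(0, n, hp.minibatch):
            batch = order[start : start + hp.minibatch]
            acc: Gradients | None = None
            for idx in batch:
                x, y = inputs[idx], targets[idx]
                fp = forward(
                    params, x, state, hp.amp1, training=True, crosses=crosses
                )
                rep = cost(params, fp.output, y, hp)
                epoch_cost += rep.data_term
                correct += _predictions_match(fp.output, y)
                g = gradients(params, x, y, fp)
                if acc is None:
                    acc = g
                else:
                    acc += g
            if len(batch) > 1:
                acc.scale(1.0 / len(batch))
            momentum_step(params, acc, mstate, hp)
        rec = EpochRecord(
            epoch=epoch,
            data_cost=epoch_cost / n,
            l2_cost=(
                hp.alpha / (2 * hp.eta) * _weight_square_sum(params)
                if hp.alpha
                else 0.0
            ),
            train_accuracy=correct / n,
        )
        if not np.isfinite(rec.data_cost):
            raise TrainingDiverged(
                f"non-finite cost {rec.data_cost} at epoch {epoch}; "
                "reduce eta or check the data"
            )
        history.append(rec)
        if callbacks:
            for cb in callbacks:
                cb(rec, params, state)
    return params, state, history


# ---------------------------------------------------------------------------
# Power-law learning curves: err = c0 / (examples/digit)^rho
# ---------------------------------------------------------------------------


@dataclass
class PowerLawFit:
    c0: float
    rho: float
    residual: float = 0.0

    def predict(self, examples_per_digit) -> np.ndarray:
        n = np.asarray(examples_per_digit, dtype=np.float64)
        out = self.c0 / n**self.rho
        return out if out.ndim else float(out)


def fit_power_law(points) -> PowerLawFit:
    """Least-squares line in log-log space through (examples/digit, error)
    points; returns c0 and the decay exponent rho."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (examples_per_digit, error) points")
    if (pts <= 0).any():
        raise ValueError("power-law fit requires positive sizes and errors")
    logn, loge = np.log(pts[:, 0]), np.log(pts[:, 1])
    slope, intercept = np.polyfit(logn, loge, 1)
    resid = float(np.sum((loge - (slope * logn + intercept)) ** 2))
    return PowerLawFit(c0=float(np.exp(intercept)), rho=float(-slope), residual=resid)
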