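"""Least-action perceptron committees.

A digit identifier is a committee of seven sign perceptrons whose outputs
(+-1) are summed with fixed unit weights. Learning is Hebbian and local in
its update, with one non-local ingredient: an update fires only when fewer
than 5 of the 7 members output the desired label, and then exactly one
perceptron — the erring one with the minimal absolute local field — moves:
W <- (1-alpha) W + eta (y - a) X, with a in {-1,+1} so eta (y - a) = +-2 eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crosses import CrossIndexSet, cross_inputs, rescale_cross_weights

COMMITTEE_SIZE = 7
CORRECT_GATE = 5  # no update when at least this many members are correct


@dataclass
class HebbianHyperparams:
    eta: float = 0.05
    alpha: float = 0.0002
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")


@dataclass
class PerceptronCommittee:
    """Weight vectors of the committee members; output weights are fixed at
    1 and never change. There is no bias term: the field is z = W . X.

    W1      : (n_members, n_inputs + n_crosses) — each row spans the regular
              inputs followed by that member's own cross features.
    crosses : optional per-member cross index set (n_units == n_members).
    """

    W1: np.ndarray
    crosses: CrossIndexSet | None = None
    gate: int = CORRECT_GATE

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        if self.crosses is not None and self.crosses.n_units != self.n_members:
            raise ValueError("cross set must have one unit per committee member")

    @property
    def n_members(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "PerceptronCommittee":
        return PerceptronCommittee(self.W1.copy(), self.crosses, self.gate)


def init_committee(
    n_inputs: int,
    seed: int,
    *,
    n_members: int = COMMITTEE_SIZE,
    crosses: CrossIndexSet | None = None,
    rescale: bool = True,
    gate: int = CORRECT_GATE,
) -> PerceptronCommittee:
    """Gaussian(0,1) weights, per-member normalized to empirical mean 0 and
    population std 1; cross weights additionally rescaled by
    sqrt(n_regular / n_crosses) for scale consistency with the
    gradient-trained cross networks."""
    rng = np.random.default_rng(seed)
    n_cross = 0 if crosses is None else crosses.n_crosses
    W = rng.standard_normal((n_members, n_inputs + n_cross))
    W = (W - W.mean(axis=1, keepdims=True)) / W.std(axis=1, keepdims=True)
    if crosses is not None and rescale and n_cross:
        W[:, n_inputs:] = rescale_cross_weights(W[:, n_inputs:], n_inputs, n_cross)
    return PerceptronCommittee(W1=W, crosses=crosses, gate=gate)


def expand_input(x: np.ndarray, committee: PerceptronCommittee) -> np.ndarray:
    """(n_members, d) matrix: row p is the regular input concatenated with
    member p's cross features."""
    x = np.asarray(x, dtype=np.float64)
    if committee.crosses is None:
        return np.broadcast_to(x, (committee.n_members, x.shape[0])).copy()
    rows = [
        np.concatenate([x, cross_inputs(x, committee.crosses, p)])
        for p in range(committee.n_members)
    ]
    return np.asarray(rows)


def perceptron_outputs(
    committee: PerceptronCommittee, x_expanded: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Member outputs in {-1, +1} (strict threshold: +1 iff z > 0, so z = 0
    maps to -1) and the local fields z."""
    z = np.einsum("pd,pd->p", committee.W1, x_expanded)
    outputs = np.where(z > 0, 1, -1).astype(np.int64)
    return outputs, z


def committee_value(committee: PerceptronCommittee, x_expanded: np.ndarray) -> int:
    outputs, _ = perceptron_outputs(committee, x_expanded)
    return int(outputs.sum())


@dataclass
class UpdateReport:
    updated: int | None  # index of the updated member, or None for a no-op
    n_correct: int
    outputs: np.ndarray
    fields: np.ndarray


def least_action_step(
    committee: PerceptronCommittee,
    x_expanded: np.ndarray,
    y: int,
    hp: HebbianHyperparams,
) -> UpdateReport:
    """One least-action presentation (in place).

    All fields are read synchronously before any change. If at least
    ``committee.gate`` members already output y, nothing changes; otherwise
    the single wrong member with minimal |z| (ties: lowest index) receives
    W <- (1-alpha) W + eta (y - a) X. Decay touches only that member, only
    on update steps.
    """
    if y not in (-1, 1):
        raise ValueError("y must be -1 or +1")
    outputs, z = perceptron_outputs(committee, x_expanded)
    n_correct = int((outputs == y).sum())
    if n_correct >= committee.gate:
        return UpdateReport(updated=None, n_correct=n_correct, outputs=outputs, fields=z)
    wrong = np.flatnonzero(outputs != y)
    p = wrong[np.argmin(np.abs(z[wrong]))]
    committee.W1[p] = (1 - hp.alpha) * committee.W1[p] + hp.eta * (
        y - outputs[p]
    ) * x_expanded[p]
    return UpdateReport(updated=int(p), n_correct=n_correct, outputs=outputs, fields=z)


@dataclass
class HebbianEpochRecord:
    epoch: int
    train_error: float
    n_updates: int


def train_committee(
    committee: PerceptronCommittee,
    inputs: np.ndarray,
    y: np.ndarray,
    hp: HebbianHyperparams,
) -> list:
    """Train one committee on +-1 labels; returns per-epoch history.

    The training error counts examples where the summed committee output has
    the wrong sign (a zero sum counts as wrong).
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64).ravel()
    rng = np.random.default_rng(hp.seed)
    history: list = []
    n = inputs.shape[0]
    expanded = None
    if committee.crosses is None:
        expanded = inputs  # rows broadcast to every member below
    for epoch in range(1, hp.epochs + 1):
        order = rng.permutation(n)
        n_updates = 0
        for idx in order:
            if expanded is None:
                x_exp = expand_input(inputs[idx], committee)
            else:
                x_exp = np.broadcast_to(
                    expanded[idx], (committee.n_members, inputs.shape[1])
                )
            rep = least_action_step(committee, x_exp, int(y[idx]), hp)
            n_updates += rep.updated is not None
        # error measured on the end-of-epoch weights
        errs = 0
        for i in range(n):
            if expanded is None:
                x_exp = expand_input(inputs[i], committee)
            else:
                x_exp = np.broadcast_to(
                    expanded[i], (committee.n_members, inputs.shape[1])
                )
            val = committee_value(committee, x_exp)
            errs += (np.sign(val) != y[i]) or (val == 0)
        history.append(
            HebbianEpochRecord(epoch=epoch, train_error=errs / n, n_updates=n_updates)
        )
        if history[-1].train_error == 0.0 and n_updates == 0:
            break  # fixed point: nothing can change any more
    return history


def train_hebbian(
    committees: dict,
    inputs: np.ndarray,
    labels: np.ndarray,
    hp: HebbianHyperparams,
) -> tuple[dict, dict]:
    """Train one identifier committee per digit, fully independently.

    ``committees`` maps digit -> PerceptronCommittee. Each identifier sees
    label +1 for its own digit and -1 otherwise, and consumes an RNG stream
    seeded by (hp.seed, digit), so training order of the identifiers is
    immaterial.
    """
    labels = np.asarray(labels, dtype=np.int64).ravel()
    histories: dict = {}
    for digit, committee in committees.items():
        y = np.where(labels == digit, 1, -1)
        hp_d = HebbianHyperparams(
            eta=hp.eta,
            alpha=hp.alpha,
            epochs=hp.epochs,
            seed=int(np.random.SeedSequence([hp.seed, int(digit)]).generate_state(1)[0] % (2**31)),
        )
        histories[digit] = train_committee(committee, inputs, y, hp_d)
    return committees, histories


def identifier_values(committees: dict, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Committee values and summed fields per digit, in digit order."""
    digits = sorted(committees)
    values = np.empty(len(digits), dtype=np.int64)
    zsums = np.empty(len(digits), dtype=np.float64)
    for i, d in enumerate(digits):
        x_exp = expand_input(x, committees[d])
        outputs, z = perceptron_outputs(committees[d], x_exp)
        values[i] = outputs.sum()
        zsums[i] = z.sum()
    return values, zsums


def predict_hebbian(committees: dict, x: np.ndarray) -> int:
    """Predicted digit: argmax of committee values across identifiers.

    Ties on the committee value are broken by the larger summed field, then
    by the lowest digit index.
    """
    digits = sorted(committees)
    values, zsums = identifier_values(committees, x)
    best = np.flatnonzero(values == values.max())
    if best.size > 1:
        zbest = zsums[best]
        best = best[np.flatnonzero(zbest == zbest.max())]
    return int(digits[best[0]])
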