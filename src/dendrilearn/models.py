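"""Model / Results objects over the low-level trainers.

``DendriticNetClassifier`` and ``HebbianCommitteeClassifier`` are built from
a normalized dataset; ``fit()`` returns a Results object carrying the
trained parameters, the per-epoch history, prediction methods and a
``summary()`` table. Identifier-style architectures (the tree network and
the Hebbian committees) train ten independent one-vs-all models and predict
by argmax of the ten outputs; the dense architectures train one ten-output
network on one-hot targets.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .crosses import CrossIndexSet, generate_crosses
from .ensemble import confusion_counts, soft_committee_predict_batch, test_error
from .hebbian import (
    HebbianHyperparams,
    identifier_values,
    init_committee,
    predict_hebbian,
    train_hebbian,
)
from .idx import NormalizedDataset
from .network import Hyperparams, forward_outputs, init_params
from .training import train


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _as_dataset(data) -> NormalizedDataset:
    if isinstance(data, NormalizedDataset):
        return data
    raise TypeError("expected a NormalizedDataset (see dendrilearn.idx.normalize)")


class DendriticNetClassifier:
    """Gradient-trained digit classifier.

    Parameters
    ----------
    train_data : NormalizedDataset
        Per-example normalized inputs with integer labels.
    architecture : str
        'fftn_identifier' (a bank of one-vs-all tree networks),
        'fully_connected_2h', or 'crosses_1h'.
    hyperparams : Hyperparams, optional
        Defaults to small-step vanilla settings; use presets for the
        published configurations.
    crosses : CrossIndexSet, optional
        Required for 'crosses_1h'.
    """

    def __init__(
        self,
        train_data: NormalizedDataset,
        architecture: str = "fully_connected_2h",
        hyperparams: Hyperparams | None = None,
        *,
        crosses: CrossIndexSet | None = None,
        n_classes: int = 10,
        n_hidden: int | None = None,
        block: int = 16,
    ) -> None:
        self.data = _as_dataset(train_data)
        self.architecture = architecture
        self.hp = hyperparams or Hyperparams(eta=0.05, epochs=10)
        self.crosses = crosses
        self.n_classes = n_classes
        self.n_hidden = n_hidden
        self.block = block
        if architecture == "crosses_1h" and crosses is None:
            raise ValueError("crosses_1h requires a CrossIndexSet")

    @property
    def is_identifier_bank(self) -> bool:
        return self.architecture == "fftn_identifier"

    def fit(self, seed: int | None = None, callbacks=None) -> "DendriticNetResults":
        """Train and return a results object. ``seed`` overrides hp.seed for
        both initialization and example ordering."""
        seed = self.hp.seed if seed is None else seed
        hp = replace(self.hp, seed=seed)
        X, labels = self.data.inputs, self.data.labels
        if self.is_identifier_bank:
            params_bank, states, histories = {}, {}, {}
            for digit in range(self.n_classes):
                dseed = int(
                    np.random.SeedSequence([seed, digit]).generate_state(1)[0] % (2**31)
                )
                p = init_params(
                    "fftn_identifier",
                    dseed,
                    n_inputs=X.shape[1],
                    block=self.block,
                )
                y = (labels == digit).astype(np.float64)
                p, st, hist = train(
                    p, X, y, replace(hp, seed=dseed), callbacks=callbacks
                )
                params_bank[digit] = p
                states[digit] = st
                histories[digit] = hist
            return DendriticNetResults(
                model=self, params=params_bank, states=states, history=histories, hp=hp
            )
        p = init_params(
            self.architecture,
            seed,
            n_inputs=X.shape[1],
            n_hidden=self.n_hidden,
            n_outputs=self.n_classes,
            crosses=self.crosses,
        )
        y = _one_hot(labels, self.n_classes)
        p, st, hist = train(p, X, y, hp, crosses=self.crosses, callbacks=callbacks)
        return DendriticNetResults(model=self, params=p, states=st, history=hist, hp=hp)


class DendriticNetResults:
    """Trained parameters + history; prediction and evaluation methods.

    The first-layer field accumulator is frozen at its end-of-training value
    and the Amp1 reduction is still applied at prediction time, keeping the
    train and test forward functions identical.
    """

    def __init__(self, model, params, states, history, hp) -> None:
        self.model = model
        self.params = params
        self.states = states
        self.history = history
        self.hp = hp

    def output_matrix(self, inputs: np.ndarray) -> np.ndarray:
        """(M, n_classes) raw output-unit values."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
        if self.model.is_identifier_bank:
            cols = [
                forward_outputs(
                    self.params[d], inputs, self.states[d], self.hp.amp1
                ).ravel()
                for d in range(self.model.n_classes)
            ]
            return np.column_stack(cols)
        return forward_outputs(
            self.params, inputs, self.states, self.hp.amp1, crosses=self.model.crosses
        )

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Predicted digits: argmax over outputs (np.argmax breaks ties at
        the lowest index)."""
        return self.output_matrix(inputs).argmax(axis=1)

    def test_error(self, test_data: NormalizedDataset) -> float:
        test_data = _as_dataset(test_data)
        return test_error(self.predict(test_data.inputs), test_data.labels)

    def history_frame(self) -> pd.DataFrame:
        if self.model.is_identifier_bank:
            rows = [
                {"identifier": d, **vars(rec)}
                for d in self.history
                for rec in self.history[d]
            ]
        else:
            rows = [vars(rec) for rec in self.history]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        hf = self.history_frame()
        last = hf[hf.epoch == hf.epoch.max()]
        lines = [
            "Dendritic network classifier",
            "=" * 48,
            f"architecture:     {self.model.architecture}",
            f"epochs:           {self.hp.epochs}",
            f"eta={self.hp.eta:g}  mu={self.hp.mu:g}  alpha={self.hp.alpha:g}  "
            f"Amp1={self.hp.amp1:g}",
            f"final data cost:  {last.data_cost.mean():.6f}",
            f"final train acc:  {last.train_accuracy.mean():.4f}",
        ]
        if self.model.is_identifier_bank:
            lines.append(f"identifiers:      {self.model.n_classes} (independent)")
        if self.model.crosses is not None:
            lines.append(
                f"input crosses:    {self.model.crosses.n_crosses} per hidden unit"
            )
        return "\n".join(lines)


class SoftCommittee:
    """Ensemble of results objects trained from different initial weights."""

    def __init__(self, replicas) -> None:
        if not replicas:
            raise ValueError("need at least one replica")
        archs = {r.model.architecture for r in replicas}
        if len(archs) > 1:
            raise ValueError("replicas must share one architecture")
        self.replicas = list(replicas)

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return soft_committee_predict_batch(
            [r.output_matrix(inputs) for r in self.replicas]
        )

    def test_error(self, test_data: NormalizedDataset) -> float:
        test_data = _as_dataset(test_data)
        return test_error(self.predict(test_data.inputs), test_data.labels)


def fit_committee(
    model_factory, n_replicas: int, base_seed: int
) -> SoftCommittee:
    """Train n_replicas copies of a model from distinct initial weights.

    ``model_factory()`` must return a fresh model; replica s is fitted with
    seed derived from (base_seed, s).
    """
    replicas = []
    for s in range(n_replicas):
        seed = int(np.random.SeedSequence([base_seed, s]).generate_state(1)[0] % (2**31))
        replicas.append(model_factory().fit(seed=seed))
    return SoftCommittee(replicas)


class HebbianCommitteeClassifier:
    """Digit classifier of ten independent least-action committees.

    Each identifier is a committee of ``n_members`` (default 7) sign
    perceptrons with unit output weights; optionally each member carries its
    own set of order-3 input crosses.
    """

    def __init__(
        self,
        train_data: NormalizedDataset,
        hyperparams: HebbianHyperparams | None = None,
        *,
        n_classes: int = 10,
        n_members: int = 7,
        n_crosses: int = 0,
        rescale_crosses: bool = True,
    ) -> None:
        self.data = _as_dataset(train_data)
        self.hp = hyperparams or HebbianHyperparams()
        self.n_classes = n_classes
        self.n_members = n_members
        self.n_crosses = n_crosses
        self.rescale_crosses = rescale_crosses

    def fit(self, seed: int | None = None) -> "HebbianCommitteeResults":
        seed = self.hp.seed if seed is None else seed
        hp = HebbianHyperparams(
            eta=self.hp.eta, alpha=self.hp.alpha, epochs=self.hp.epochs, seed=seed
        )
        X, labels = self.data.inputs, self.data.labels
        committees = {}
        for digit in range(self.n_classes):
            dseed = int(
                np.random.SeedSequence([seed, digit, 7]).generate_state(1)[0] % (2**31)
            )
            crosses = None
            if self.n_crosses:
                crosses = generate_crosses(
                    X.shape[1], self.n_crosses, self.n_members, X, dseed
                )
            committees[digit] = init_committee(
                X.shape[1],
                dseed,
                n_members=self.n_members,
                crosses=crosses,
                rescale=self.rescale_crosses,
            )
        committees, histories = train_hebbian(committees, X, labels, hp)
        return HebbianCommitteeResults(
            model=self, committees=committees, history=histories, hp=hp
        )


class HebbianCommitteeResults:
    def __init__(self, model, committees, history, hp) -> None:
        self.model = model
        self.committees = committees
        self.history = history
        self.hp = hp

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
        return np.asarray([predict_hebbian(self.committees, x) for x in inputs])

    def output_matrix(self, inputs: np.ndarray) -> np.ndarray:
        """(M, n_classes) committee values (sums of +-1 member outputs)."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
        return np.asarray(
            [identifier_values(self.committees, x)[0] for x in inputs], dtype=np.float64
        )

    def test_error(self, test_data: NormalizedDataset) -> float:
        test_data = _as_dataset(test_data)
        return test_error(self.predict(test_data.inputs), test_data.labels)

    def confusion(self, test_data: NormalizedDataset) -> np.ndarray:
        test_data = _as_dataset(test_data)
        return confusion_counts(
            self.predict(test_data.inputs), test_data.labels, self.model.n_classes
        )

    def history_frame(self) -> pd.DataFrame:
        rows = [
            {"identifier": d, **vars(rec)}
            for d in self.history
            for rec in self.history[d]
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        hf = self.history_frame()
        final = hf.groupby("identifier").last()
        lines = [
            "Hebbian least-action committee classifier",
            "=" * 48,
            f"identifiers:      {self.model.n_classes} x {self.model.n_members} perceptrons",
            f"eta={self.hp.eta:g}  alpha={self.hp.alpha:g}  epochs={self.hp.epochs}",
            f"crosses/member:   {self.model.n_crosses}",
            f"final mean per-identifier train error: {final.train_error.mean():.4f}",
        ]
        return "\n".join(lines)
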