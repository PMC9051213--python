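"""Published hyperparameter presets for the three gradient-trained
architectures and the Hebbian committees.

The ``nocross-*`` and ``crosses-*`` presets are the per-training-set-size
optima reported for the one-hidden-layer momentum runs without and with the
10,000 order-3 input crosses; ``fc2h-50k`` is the full-dataset
two-hidden-layer run (the only one using minibatch averaging);
``fftn-identifier`` is the 784-49-1 tree-network digit identifier.
"""

from __future__ import annotations

from dataclasses import replace

from .hebbian import HebbianHyperparams
from .network import Hyperparams

HYPERPARAM_PRESETS: dict = {
    "fftn-identifier": Hyperparams(
        eta=0.023, mu=0.998, alpha=2e-7, amp1=0.1, epochs=50
    ),
    "fc2h-50k": Hyperparams(
        eta=0.03, mu=0.9998, alpha=0.0079, amp1=0.0001, epochs=300, minibatch=200
    ),
    "nocross-15pd": Hyperparams(eta=0.0004, mu=0.95, alpha=0.005, amp1=0.1, epochs=300),
    "nocross-30pd": Hyperparams(
        eta=0.0054, mu=0.978, alpha=0.0003, amp1=0.000095, epochs=300
    ),
    "nocross-60pd": Hyperparams(
        eta=0.0000089, mu=0.9999, alpha=0.00017, amp1=0.0000975, epochs=300
    ),
    "crosses-15pd": Hyperparams(
        eta=0.0079, mu=0.63, alpha=0.00018, amp1=0.07, epochs=200
    ),
    "crosses-30pd": Hyperparams(eta=0.008, mu=0.773, alpha=0.00047, amp1=0.05, epochs=200),
    "crosses-60pd": Hyperparams(
        eta=0.00047, mu=0.961, alpha=0.00028, amp1=0.1, epochs=200
    ),
    "crosses-90pd": Hyperparams(
        eta=0.0003, mu=0.99555, alpha=0.0001, amp1=0.09, epochs=200
    ),
}

HEBBIAN_PRESET = HebbianHyperparams(eta=0.05, alpha=0.0002, epochs=50)


def get_preset(name: str) -> Hyperparams:
    """Return an independent copy of a named preset."""
    try:
        return replace(HYPERPARAM_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(HYPERPARAM_PRESETS)}"
        ) from None
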