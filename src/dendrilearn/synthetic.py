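"""Synthetic digit-shaped datasets and teacher models.

Every learner in the package is exercised on generated data shaped like the
handwritten-digit corpus it targets: 28x28 uint8 grayscale images in
[0, 255] with class-conditional structure and a configurable number of
pixels held constant across the training set (real scans have a constant
border, which the zero-variance masking rule exists for). Prototypes are
low-frequency random fields rather than digit glyphs — the algorithms need
class structure, not legible shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .idx import RawDataset


@dataclass
class SyntheticSpec:
    """Desk-scale generator settings.

    prototype_contrast : std (in gray levels) of each class's smooth
                         prototype around mid-gray
    noise_std          : per-pixel Gaussian noise (gray levels) added to the
                         prototype for every example
    n_constant_pixels  : pixels forced to one fixed value across the whole
                         train (and test) set, exercising zero-variance
                         masking
    """

    n_classes: int = 10
    n_per_class_train: int = 100
    n_per_class_test: int = 50
    image_side: int = 28
    prototype_contrast: float = 70.0
    noise_std: float = 25.0
    n_constant_pixels: int = 10
    smooth_sigma: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_per_class_train, self.image_side) < 1:
            raise ValueError("spec fields must be positive")
        if self.n_constant_pixels >= self.image_side**2:
            raise ValueError("n_constant_pixels must be below image_side**2")


@dataclass
class TeacherCommittee:
    """A majority-vote labeling rule over 7 random sign perceptrons."""

    W: np.ndarray  # (7, n_inputs)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if not self.W.any(axis=1).all():
            raise ValueError("teacher perceptrons must be nondegenerate")


def _prototype(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    raw = rng.standard_normal((spec.image_side, spec.image_side))
    smooth = gaussian_filter(raw, sigma=spec.smooth_sigma)
    smooth = (smooth - smooth.mean()) / smooth.std()
    return 128.0 + spec.prototype_contrast * smooth


def _render(
    rng: np.random.Generator, protos, spec: SyntheticSpec, n_per_class: int
) -> RawDataset:
    images, labels = [], []
    for cls, proto in enumerate(protos):
        noise = rng.standard_normal((n_per_class,) + proto.shape) * spec.noise_std
        batch = np.clip(proto[np.newaxis] + noise, 0, 255).astype(np.uint8)
        images.append(batch.reshape(n_per_class, -1))
        labels.append(np.full(n_per_class, cls, dtype=np.int64))
    return RawDataset(
        images=np.concatenate(images),
        labels=np.concatenate(labels),
        rows=spec.image_side,
        cols=spec.image_side,
    )


def gen_images(
    spec: SyntheticSpec, *, ensure_exact_mask: bool = True
) -> tuple[RawDataset, RawDataset]:
    """Deterministic (train, test) pair for a spec + seed.

    Exactly ``n_constant_pixels`` randomly chosen pixels carry one fixed
    value across every train and test example. With ``ensure_exact_mask``
    (default) any OTHER pixel that happens to be constant across the train
    set is nudged by one gray level in the first example, so the
    zero-variance mask marks precisely the designated pixels.
    """
    rng = np.random.default_rng(spec.seed)
    protos = [_prototype(rng, spec) for _ in range(spec.n_classes)]
    train = _render(rng, protos, spec, spec.n_per_class_train)
    test = _render(rng, protos, spec, spec.n_per_class_test)

    n_pix = spec.image_side**2
    const_idx = rng.choice(n_pix, size=spec.n_constant_pixels, replace=False)
    const_val = rng.integers(0, 256, size=spec.n_constant_pixels, dtype=np.int64)
    train.images[:, const_idx] = const_val
    test.images[:, const_idx] = const_val

    if ensure_exact_mask:
        designated = np.zeros(n_pix, dtype=bool)
        designated[const_idx] = True
        accidental = (train.images == train.images[0]).all(axis=0) & ~designated
        for p in np.flatnonzero(accidental):
            v = int(train.images[0, p])
            train.images[0, p] = v - 1 if v > 0 else v + 1
    return train, test


def make_teacher(n_inputs: int, seed: int, n_members: int = 7) -> TeacherCommittee:
    rng = np.random.default_rng(seed)
    return TeacherCommittee(W=rng.standard_normal((n_members, n_inputs)))


def gen_teacher_labels(x: np.ndarray, teacher: TeacherCommittee) -> np.ndarray:
    """+-1 labels by majority vote of the teacher's sign perceptrons
    (strict threshold: field > 0 votes +1, else -1; an odd committee never
    ties)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    votes = np.where(x @ teacher.W.T > 0, 1, -1)
    return np.sign(votes.sum(axis=1)).astype(np.int64)


def gen_separable(
    n: int, dim: int, margin: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance Gaussian clouds with centers 2*margin apart along a
    random direction; labels in {0, 1}, balanced to within one example."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    y = np.zeros(n, dtype=np.int64)
    y[n // 2 :] = 1
    x = rng.standard_normal((n, dim))
    x += np.where(y[:, np.newaxis] == 1, margin, -margin) * direction[np.newaxis, :]
    perm = rng.permutation(n)
    return x[perm], y[perm]
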