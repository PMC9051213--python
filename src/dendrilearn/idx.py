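"""IDX container I/O (the MNIST dialect) and per-example input normalization.

The IDX format stores a big-endian magic number whose low byte encodes the
number of dimensions (0x00000801 = unsigned-byte labels, 1 dim;
0x00000803 = unsigned-byte images, 3 dims), followed by one big-endian
uint32 per dimension and the raw uint8 payload.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MAGIC_LABELS = 0x00000801
MAGIC_IMAGES = 0x00000803


class IdxFormatError(ValueError):
    """Raised for malformed or unsupported IDX files."""


@dataclass
class RawDataset:
    """Raw examples as stored on disk: uint8 pixels in [0, 255].

    images : (M, P) uint8 matrix, rows flattened row-major (P = rows*cols)
    labels : (M,) integers in [0, 9]
    """

    images: np.ndarray
    labels: np.ndarray
    rows: int = 28
    cols: int = 28

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.images.ndim == 3:
            m, r, c = self.images.shape
            self.rows, self.cols = r, c
            self.images = self.images.reshape(m, r * c)
        if self.images.ndim != 2:
            raise ValueError("images must be (M, P) or (M, rows, cols)")
        if self.images.shape[1] != self.rows * self.cols:
            raise ValueError(
                f"P={self.images.shape[1]} does not match rows*cols="
                f"{self.rows * self.cols}"
            )
        if self.images.shape[0] != self.labels.shape[0]:
            raise ValueError("images and labels disagree on the number of examples")

    @property
    def n_examples(self) -> int:
        return self.images.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.images.shape[1]


@dataclass
class NormalizedDataset:
    """Per-example normalized inputs: each row has mean 0 and std 1
    (population convention) before zero-variance masking.

    inputs             : (M, P) float64
    labels             : (M,) integers
    zero_variance_mask : (P,) bool — True where the pixel was constant across
                         the *training* set; such pixels are exactly 0 here.
    """

    inputs: np.ndarray
    labels: np.ndarray
    zero_variance_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.zero_variance_mask is None:
            self.zero_variance_mask = np.zeros(self.inputs.shape[1], dtype=bool)
        self.zero_variance_mask = np.asarray(self.zero_variance_mask, dtype=bool)

    @property
    def n_examples(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.inputs.shape[1]


def read_idx(path) -> np.ndarray:
    """Read one IDX file.

    Returns a (M,) uint8 vector for label files and a (M, rows, cols)
    uint8 array for image files.
    """
    data = Path(path).read_bytes()
    if len(data) < 4:
        raise IdxFormatError(f"{path}: file too short for a magic number")
    (magic,) = struct.unpack(">I", data[:4])
    if magic == MAGIC_LABELS:
        ndim = 1
    elif magic == MAGIC_IMAGES:
        ndim = 3
    else:
        raise IdxFormatError(f"{path}: unsupported magic number 0x{magic:08x}")
    header_len = 4 + 4 * ndim
    if len(data) < header_len:
        raise IdxFormatError(f"{path}: truncated header")
    dims = struct.unpack(f">{ndim}I", data[4:header_len])
    expected = int(np.prod(dims, dtype=np.int64))
    payload = data[header_len:]
    if len(payload) != expected:
        raise IdxFormatError(
            f"{path}: payload has {len(payload)} bytes, expected {expected} "
            f"for dims {dims}"
        )
    arr = np.frombuffer(payload, dtype=np.uint8)
    return arr.reshape(dims) if ndim > 1 else arr.copy()


def write_idx(array: np.ndarray, path) -> Path:
    """Write a uint8 array as an IDX file.

    1-D arrays become label files (magic 0x801); (M, rows, cols) arrays
    become image files (magic 0x803). Values must lie in [0, 255].
    """
    arr = np.asarray(array)
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("IDX payload values must lie in [0, 255]")
    arr = arr.astype(np.uint8)
    if arr.ndim == 1:
        magic, dims = MAGIC_LABELS, arr.shape
    elif arr.ndim == 3:
        magic, dims = MAGIC_IMAGES, arr.shape
    else:
        raise ValueError("expected a 1-D label vector or (M, rows, cols) images")
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">I", magic))
        fh.write(struct.pack(f">{len(dims)}I", *dims))
        fh.write(arr.tobytes())
    return path


def load_dataset(images_path, labels_path) -> RawDataset:
    """Read an images/labels IDX pair into a RawDataset."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim != 3:
        raise IdxFormatError(f"{images_path}: expected an image file")
    if labels.ndim != 1:
        raise IdxFormatError(f"{labels_path}: expected a label file")
    return RawDataset(images=images, labels=labels)


def write_dataset(dataset: RawDataset, images_path, labels_path) -> None:
    """Write a RawDataset as an images/labels IDX pair."""
    write_idx(dataset.images.reshape(-1, dataset.rows, dataset.cols), images_path)
    write_idx(dataset.labels.astype(np.uint8), labels_path)


def zero_variance_mask(train: RawDataset) -> np.ndarray:
    """True for every pixel that takes a single value across all training
    examples (constancy, not zero-ness, is the criterion)."""
    if train.n_examples < 1:
        raise ValueError("need at least one training example")
    img = train.images
    return (img == img[0]).all(axis=0)


def normalize(
    dataset: RawDataset,
    mask: np.ndarray | None = None,
    *,
    ddof: int = 0,
) -> NormalizedDataset:
    """Per-example normalization followed by zero-variance masking.

    Each example has its own pixel mean subtracted and is divided by its own
    pixel std (population convention by default, ``ddof=0``); masked pixels
    are then set to exactly 0. The mask must come from the training set and
    is applied unchanged to test data.

    A degenerate constant example (std 0) is emitted as all zeros with a
    warning; this cannot occur for real handwritten-digit data.
    """
    x = dataset.images.astype(np.float64)
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = std[:, 0] == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant example(s) normalized to all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        std = np.where(std == 0.0, 1.0, std)
    out = (x - mean) / std
    out[degenerate] = 0.0
    if mask is None:
        mask = np.zeros(dataset.n_pixels, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out[:, mask] = 0.0
    return NormalizedDataset(inputs=out, labels=dataset.labels, zero_variance_mask=mask)


def normalize_pair(
    train: RawDataset, test: RawDataset, *, ddof: int = 0
) -> tuple[NormalizedDataset, NormalizedDataset]:
    """Normalize train and test with the train-derived zero-variance mask."""
    mask = zero_variance_mask(train)
    return normalize(train, mask, ddof=ddof), normalize(test, mask, ddof=ddof)
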