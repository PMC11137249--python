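"""Seeded generators for every input the experiments need.

Two toy classification sets drive the rate-network experiments: a linearly
separable cloud on the unit square and a noisy XOR arrangement of four
Gaussian clusters.  Both return features in ``[0, 1]^2`` and one-hot
labels, with a fixed train/test split, and are fully determined by their
seed.  A separate generator produces the (input, target) stream used to
pre-train the auxiliary reservoir: random inputs, labels and layer
activities paired with the exact modulation signal computed over a rolling
working-memory buffer.

Benchmark image sets (MNIST, CIFAR-10) sit behind an optional loader that
requires the data to be present locally; nothing in the core package or
its tests depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hsic_core import KernelParams
from .plasticity import SampleMemory, modulation_signal

__all__ = [
    "LabeledDataset",
    "ExternalDataError",
    "gen_linear",
    "gen_xor",
    "gen_reservoir_stream",
    "load_benchmark",
]


@dataclass(frozen=True)
class LabeledDataset:
    """Features in [0,1]^d, one-hot labels and a train/test split."""

    X: np.ndarray  # (n, d)
    y: np.ndarray  # (n, c) one-hot
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test splits overlap")

    @property
    def labels(self) -> np.ndarray:
        """Integer class labels."""
        return self.y.argmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"x{i}" for i in range(self.X.shape[1])])
        df["label"] = self.labels
        df["split"] = "train"
        df.loc[self.test_idx, "split"] = "test"
        return df


class ExternalDataError(FileNotFoundError):
    """Raised when an optional benchmark dataset is not available locally."""


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def _split(n: int, n_test: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def gen_linear(
    n: int = 1000, n_test: int = 100, seed: int = 0
) -> LabeledDataset:
    """Linearly separable binary points uniform on the unit square.

    The boundary is a hyperplane through the square's centre with a
    seed-drawn normal direction, so every dataset admits a zero-error
    linear classifier by construction.
    """
    if n <= n_test:
        raise ValueError("need n > n_test")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, 2))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    normal = np.array([np.cos(theta), np.sin(theta)])
    labels = ((x - 0.5) @ normal > 0).astype(int)
    train_idx, test_idx = _split(n, n_test, rng)
    return LabeledDataset(
        X=x, y=_one_hot(labels, 2), train_idx=train_idx, test_idx=test_idx, seed=seed
    )


def gen_xor(
    n: int = 1000, n_test: int = 100, noise_sd: float = 0.1, seed: int = 0
) -> LabeledDataset:
    """Noisy XOR: Gaussian clusters at the unit-square corners.

    Samples are drawn in equal rotation from centres (0,0), (0,1), (1,0),
    (1,1) with isotropic noise, clipped back to the unit square; the label
    is the XOR of the centre coordinates, so no linear classifier can do
    much better than 75% at small noise.
    """
    if n <= n_test:
        raise ValueError("need n > n_test")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    which = np.tile(np.arange(4), n // 4 + 1)[:n]
    x = centers[which] + rng.normal(0.0, noise_sd, size=(n, 2))
    x = np.clip(x, 0.0, 1.0)
    labels = (centers[which, 0].astype(int) ^ centers[which, 1].astype(int))
    train_idx, test_idx = _split(n, n_test, rng)
    return LabeledDataset(
        X=x, y=_one_hot(labels, 2), train_idx=train_idx, test_idx=test_idx, seed=seed
    )


def gen_reservoir_stream(
    n_samples: int = 100,
    input_dim: int = 16,
    z_dim: int = 10,
    n_classes: int = 10,
    N: int = 10,
    params: KernelParams | None = None,
    seed: int = 0,
    X: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """Stream of (reservoir input, true modulation signal) pairs.

    Inputs are uniform random feature vectors (or externally supplied rows
    ``X``), labels uniform one-hot, hidden activities ``z`` uniform on
    ``[0, 1]^z_dim``.  Each reservoir input is the concatenation
    ``[x; y; z]`` — exactly the quantities a working memory must buffer.
    The target is the modulation signal computed over a rolling buffer of
    the last ``N`` samples; the first ``N - 1`` entries carry target
    ``None`` (warm-up: the buffer is not yet populated).
    """
    if params is None:
        params = KernelParams(sigma_x=0.5, sigma_z=0.5, sigma_y=0.5, gamma=2.0)
    if n_samples < N:
        raise ValueError("need n_samples >= N")
    rng = np.random.default_rng(seed)
    if X is None:
        X = rng.uniform(0.0, 1.0, size=(n_samples, input_dim))
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[0] < n_samples:
            raise ValueError("supplied X has fewer rows than n_samples")
        X = X[:n_samples]
        input_dim = X.shape[1]
    y = _one_hot(rng.integers(0, n_classes, size=n_samples), n_classes)
    z = rng.uniform(0.0, 1.0, size=(n_samples, z_dim))
    mem = SampleMemory(N)
    stream: list[tuple[np.ndarray, np.ndarray | None]] = []
    for i in range(n_samples):
        mem.push(X[i], y[i], z[i])
        target = modulation_signal(mem, params).xi if mem.full else None
        stream.append((np.concatenate([X[i], y[i], z[i]]), target))
    return stream


# ----------------------------- benchmarks ------------------------------


def load_benchmark(name: str, path: str | Path) -> LabeledDataset:
    """Load MNIST or CIFAR-10 from a local directory (optional, external).

    MNIST is read from the standard IDX files, CIFAR-10 from the python
    pickle batches.  Features are scaled to [0, 1]; labels one-hot; the
    official train/test split is kept.  Raises :class:`ExternalDataError`
    when the files are absent — the core test suite never calls this.
    """
    path = Path(path)
    if name == "mnist":
        return _load_mnist(path)
    if name == "cifar10":
        return _load_cifar10(path)
    raise ValueError(f"unknown benchmark {name!r}")


def _read_idx(path: Path) -> np.ndarray:
    if not path.exists():
        raise ExternalDataError(
            f"external data required: {path} not found; download it separately"
        )
    with open(path, "rb") as fh:
        magic = int.from_bytes(fh.read(4), "big")
        ndim = magic & 0xFF
        shape = [int.from_bytes(fh.read(4), "big") for _ in range(ndim)]
        return np.frombuffer(fh.read(), dtype=np.uint8).reshape(shape)


def _load_mnist(root: Path) -> LabeledDataset:
    xs, ys = [], []
    for stem in ("train", "t10k"):
        xs.append(_read_idx(root / f"{stem}-images-idx3-ubyte").reshape(-1, 784))
        ys.append(_read_idx(root / f"{stem}-labels-idx1-ubyte"))
    x = np.concatenate(xs).astype(float) / 255.0
    labels = np.concatenate(ys).astype(int)
    n_train = xs[0].shape[0]
    n = x.shape[0]
    return LabeledDataset(
        X=x,
        y=_one_hot(labels, 10),
        train_idx=np.arange(n_train),
        test_idx=np.arange(n_train, n),
        seed=0,
    )


def _load_cifar10(root: Path) -> LabeledDataset:
    import pickle

    batches = [f"data_batch_{i}" for i in range(1, 6)] + ["test_batch"]
    xs, ys = [], []
    for name in batches:
        p = root / name
        if not p.exists():
            raise ExternalDataError(
                f"external data required: {p} not found; download it separately"
            )
        with open(p, "rb") as fh:
            d = pickle.load(fh, encoding="bytes")
        xs.append(np.asarray(d[b"data"]))
        ys.append(np.asarray(d[b"labels"]))
    x = np.concatenate(xs).astype(float) / 255.0
    labels = np.concatenate(ys).astype(int)
    n_train = 50000
    return LabeledDataset(
        X=x,
        y=_one_hot(labels, 10),
        train_idx=np.arange(n_train),
        test_idx=np.arange(n_train, x.shape[0]),
        seed=0,
    )
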