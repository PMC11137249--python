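"""Gaussian kernels, Gram matrices and HSIC estimators.

The Hilbert-Schmidt Independence Criterion (HSIC) is a kernel dependence
measure used here as a proxy for mutual information.  Each hidden layer of a
feedforward network is trained to minimise an information-bottleneck
objective

    HSIC(X, Z) - gamma * HSIC(Y, Z)

where ``X`` is the input, ``Y`` the (one-hot) label and ``Z`` the layer
output.  Two flavours of the objective live here:

* :func:`hsic_objective` — the trace-form statistical estimator built from
  double-centered Gram matrices.  This is the quantity reported in training
  traces.
* :func:`hsic_diag_objective` — the diagonal surrogate built from
  per-sample "surprise" terms ``1 - mean_n k(x_p, x_n)``.  Differentiating
  this surrogate (with past layer outputs held fixed) yields the
  three-factor plasticity rule implemented in :mod:`ibhebb.plasticity`.

All kernels are Gaussian with the convention ``k(a, b) =
exp(-||a - b||^2 / sigma^2)`` (the bandwidth enters squared, without the
factor of two used by some texts).  Inputs are expected on the scale the
data module produces (features in ``[0, 1]``); the published bandwidths are
tuned to that scale, so no internal standardisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "gaussian_kernel",
    "gram",
    "center_rows",
    "double_center",
    "hsic_estimate",
    "hsic_objective",
    "hsic_diag_objective",
    "surprise",
    "surprise_all",
]


@dataclass(frozen=True)
class KernelParams:
    """Kernel bandwidths and the information-bottleneck balance.

    Parameters
    ----------
    sigma_x, sigma_z, sigma_y
        Gaussian bandwidths for the input, hidden-layer and label kernels.
    gamma
        Weight of the label-dependence term in the bottleneck objective;
        larger values favour retaining label information over compressing
        the input.
    """

    sigma_x: float
    sigma_z: float
    sigma_y: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_z", "sigma_y", "gamma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")


def _as_2d(samples: np.ndarray) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D sample array, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("empty sample list")
    return arr


def gaussian_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> float:
    """Evaluate ``exp(-||a - b||^2 / sigma^2)`` for two vectors."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    d2 = float(np.sum((a - b) ** 2))
    return float(np.exp(-d2 / sigma**2))


def gram(samples: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise Gaussian kernel matrix ``K[p, q] = k(x_p, x_q, sigma)``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma!r}")
    arr = _as_2d(samples)
    d2 = cdist(arr, arr, metric="sqeuclidean")
    k = np.exp(-d2 / sigma**2)
    # cdist round-off can leave the diagonal a hair below 1
    np.fill_diagonal(k, 1.0)
    return k


def center_rows(k: np.ndarray) -> np.ndarray:
    """Subtract each row's mean; every output row sums to zero.

    This is the one-sided centering whose diagonal gives the per-sample
    surprise signal.
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {k.shape}")
    return k - k.mean(axis=1, keepdims=True)


def double_center(k: np.ndarray) -> np.ndarray:
    """Apply the centering projector on both sides: ``H K H``.

    ``H = I - (1/N) 11^T``.  Rows and columns of the result each sum to
    zero.
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[0] != k.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {k.shape}")
    row = k.mean(axis=1, keepdims=True)
    col = k.mean(axis=0, keepdims=True)
    return k - row - col + k.mean()


def hsic_estimate(
    x: np.ndarray, y: np.ndarray, sigma_x: float, sigma_y: float
) -> float:
    """Biased trace-form HSIC estimator ``(N-1)^-2 tr(K_X H K_Y H)``.

    Symmetric in its arguments and nonnegative for Gaussian kernels (both
    centered Gram matrices are positive semidefinite).
    """
    x = _as_2d(x)
    y = _as_2d(y)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"sample count mismatch: {n} vs {y.shape[0]}")
    if n < 2:
        raise ValueError("HSIC estimator needs at least 2 samples")
    kx = double_center(gram(x, sigma_x))
    ky = double_center(gram(y, sigma_y))
    return float(np.sum(kx * ky) / (n - 1) ** 2)


def hsic_objective(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, params: KernelParams
) -> float:
    """Layer-wise bottleneck ``HSIC(X, Z) - gamma * HSIC(Y, Z)``."""
    return hsic_estimate(x, z, params.sigma_x, params.sigma_z) - params.gamma * (
        hsic_estimate(y, z, params.sigma_y, params.sigma_z)
    )


def surprise_all(samples: np.ndarray, sigma: float) -> np.ndarray:
    """Per-sample surprise ``1 - (1/N) sum_n k(x_p, x_n)`` for every p.

    The diagonal of the row-centered Gram matrix.  Zero when a sample is
    identical to all others; approaches 1 for a sample far from the rest.
    The self-term ``n = p`` is included in the mean.
    """
    k = gram(samples, sigma)
    return 1.0 - k.mean(axis=1)


def surprise(p: int, samples: np.ndarray, sigma: float) -> float:
    """Surprise of the sample at index ``p`` relative to the whole set."""
    arr = _as_2d(samples)
    n = arr.shape[0]
    if not -n <= p < n:
        raise IndexError(f"sample index {p} out of range for {n} samples")
    return float(surprise_all(arr, sigma)[p])


def hsic_diag_objective(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, params: KernelParams
) -> float:
    """Diagonal surrogate of the bottleneck objective.

    ``(N-1)^-2 sum_p [surprise(x_p) - gamma * surprise(y_p)] * surprise(z_p)``

    This is the quantity the three-factor plasticity rule actually
    descends: its gradient with respect to the layer parameters, taken with
    the stored past outputs frozen, factorises into the local term beta and
    the global modulation xi.
    """
    x = _as_2d(x)
    y = _as_2d(y)
    z = _as_2d(z)
    n = x.shape[0]
    if not (y.shape[0] == z.shape[0] == n):
        raise ValueError("sample count mismatch")
    if n < 2:
        raise ValueError("needs at least 2 samples")
    w = surprise_all(x, params.sigma_x) - params.gamma * surprise_all(y, params.sigma_y)
    return float(np.sum(w * surprise_all(z, params.sigma_z)) / (n - 1) ** 2)
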