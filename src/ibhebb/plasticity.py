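"""The three-factor synaptic update and its working-memory buffer.

The layer-wise bottleneck loss factorises, once past layer outputs are
treated as fixed quantities held in a buffer, into

    dW  ∝  beta ⊙ xi

where ``beta`` is purely local (the activation-derivative gate of the
current post-synaptic drive times the current pre-synaptic activity) and
``xi`` is a per-neuron global modulation assembled from the buffer of the
last ``N`` samples:

    xi = 2 / (sigma_z^2 N (N-1)^2) * [ sum_{p=1}^{N-1} w_p alpha(z_p)
                                       + w_0 sum_{p=1}^{N-1} alpha(z_p) ]

with the similarity drive ``alpha(z_p) = k(z_0, z_p) (z_0 - z_p)`` and the
surprise weights ``w_p = surprise_x(p) - gamma * surprise_y(p)``.  A
surprising input with an unsurprising label strengthens the drive pulling
representations together (compression); the reverse flips its sign and
pushes them apart.

``assemble_update`` is *exactly* the gradient of the diagonal surrogate
objective (:func:`ibhebb.hsic_core.hsic_diag_objective`) when the stored
past outputs are frozen — the buffer makes the rule Hebbian because the
current weights are assumed not to rewrite history.  The exact,
unapproximated gradient of the trace-form objective is provided as a
validation oracle in :func:`full_hsic_gradient`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsic_core import KernelParams, double_center, gram, surprise_all
from .layers import ACTIVATIONS, LayerState

__all__ = [
    "SampleMemory",
    "MemoryRecord",
    "LocalFactor",
    "ModulationSignal",
    "memory_push",
    "alpha",
    "modulation_signal",
    "local_factor",
    "assemble_update",
    "full_hsic_gradient",
]


@dataclass(frozen=True)
class MemoryRecord:
    """One buffered sample: network input, one-hot label, layer output.

    ``z_in`` (the layer's own input for that sample) is kept alongside so
    the exact-gradient oracle can recompute outputs under perturbed
    weights; the plasticity rule itself never reads past ``z_in``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    z_in: np.ndarray | None = None


class SampleMemory:
    """Ring buffer of the last ``capacity`` samples (the effective batch).

    Index 0 is the current sample; index ``-p`` is the sample presented
    ``p`` steps in the past.  Insertion evicts the oldest record once the
    buffer is full.
    """

    def __init__(self, capacity: int):
        if capacity < 2:
            raise ValueError("capacity (effective batch size) must be >= 2")
        self.capacity = capacity
        self._entries: deque[MemoryRecord] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, index: int) -> MemoryRecord:
        # 0 = current, -p = p steps back
        if index > 0 or -index >= len(self._entries):
            raise IndexError(f"memory index {index} out of range")
        return self._entries[-index]

    @property
    def full(self) -> bool:
        return len(self) == self.capacity

    def push(
        self,
        x: np.ndarray,
        y: np.ndarray,
        z: np.ndarray,
        z_in: np.ndarray | None = None,
    ) -> "SampleMemory":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        if self._entries:
            head = self._entries[0]
            for new, old, name in ((x, head.x, "x"), (y, head.y, "y"), (z, head.z, "z")):
                if new.shape != old.shape:
                    raise ValueError(
                        f"{name} shape {new.shape} does not match stored {old.shape}"
                    )
        self._entries.appendleft(
            MemoryRecord(x, y, z, None if z_in is None else np.asarray(z_in, float))
        )
        return self

    def stack(self, field: str) -> np.ndarray:
        """Stored vectors as an array, row 0 = current sample."""
        return np.stack([getattr(r, field) for r in self._entries])

    def to_frame(self) -> pd.DataFrame:
        """Flat table of the buffer contents (one row per stored sample)."""
        rows = []
        for p, r in enumerate(self._entries):
            row: dict[str, float] = {"lag": -p}
            row.update({f"x{i}": v for i, v in enumerate(r.x)})
            row.update({f"y{i}": v for i, v in enumerate(r.y)})
            row.update({f"z{i}": v for i, v in enumerate(r.z)})
            rows.append(row)
        return pd.DataFrame(rows)


def memory_push(
    mem: SampleMemory,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    z_in: np.ndarray | None = None,
) -> SampleMemory:
    """Insert a sample at index 0, evicting the oldest when full."""
    return mem.push(x, y, z, z_in)


@dataclass(frozen=True)
class LocalFactor:
    """The Hebbian factor beta: post-synaptic gate and pre-synaptic activity."""

    post_gate: np.ndarray
    pre_activity: np.ndarray


@dataclass(frozen=True)
class ModulationSignal:
    """The layer-wise global factor xi, one entry per output neuron."""

    xi: np.ndarray


def alpha(z0: np.ndarray, zp: np.ndarray, sigma_z: float) -> np.ndarray:
    """Similarity drive ``k(z0, zp) (z0 - zp)``.

    Pulls the current representation toward (or, with a negative modulating
    weight, away from) a buffered one, with strength weighted by their
    kernel similarity.
    """
    z0 = np.asarray(z0, dtype=float)
    zp = np.asarray(zp, dtype=float)
    if z0.shape != zp.shape:
        raise ValueError("z0 and zp must have the same shape")
    d2 = float(np.sum((z0 - zp) ** 2))
    return np.exp(-d2 / sigma_z**2) * (z0 - zp)


def modulation_signal(mem: SampleMemory, params: KernelParams) -> ModulationSignal:
    """Assemble xi from the buffer contents.

    Requires at least two buffered samples (warm-up: no update before
    that).  The surprise means run over the buffer's own current contents,
    self-term included, so a buffer of identical samples yields exactly
    zero modulation.
    """
    n = len(mem)
    if n < 2:
        raise ValueError("modulation signal needs at least 2 buffered samples")
    xs = mem.stack("x")
    ys = mem.stack("y")
    zs = mem.stack("z")
    w = surprise_all(xs, params.sigma_x) - params.gamma * surprise_all(
        ys, params.sigma_y
    )
    z0 = zs[0]
    diffs = z0[None, :] - zs  # row p: z0 - z_{-p}; row 0 is zero
    k = np.exp(-np.sum(diffs**2, axis=1) / params.sigma_z**2)
    a = k[:, None] * diffs  # alpha(z_p) for every lag; a[0] = 0
    past = a[1:]
    bracket = w[1:] @ past + w[0] * past.sum(axis=0)
    xi = (2.0 / (params.sigma_z**2 * n * (n - 1) ** 2)) * bracket
    return ModulationSignal(xi=xi)


def local_factor(layer: LayerState, z_in: np.ndarray) -> LocalFactor:
    """Compute beta for the current sample.

    The post-synaptic gate is the activation derivative at the current
    drive: the membrane potential for rate layers, ``W z_in + b`` for
    dense layers.
    """
    z_in = np.asarray(z_in, dtype=float)
    if layer.kind == "rate":
        drive = layer.u
    elif layer.kind == "dense":
        drive = layer.W @ z_in + layer.b
    else:
        raise ValueError(f"no local factor registered for layer kind {layer.kind!r}")
    _, dphi = ACTIVATIONS[layer.activation]
    return LocalFactor(post_gate=dphi(drive), pre_activity=z_in)


def assemble_update(
    beta: LocalFactor, xi: ModulationSignal
) -> tuple[np.ndarray, np.ndarray]:
    """Three-factor weight update ``dW_ij = xi_i gate_i pre_j``.

    Returned as a descent direction: the optimizer applies
    ``theta <- theta - eta * delta``.
    """
    g = np.asarray(xi.xi, dtype=float) * beta.post_gate
    if g.shape != beta.post_gate.shape:
        raise ValueError("xi length must equal the number of output neurons")
    return np.outer(g, beta.pre_activity), g


def full_hsic_gradient(
    mem: SampleMemory, layer: LayerState, params: KernelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradient of the trace-form bottleneck objective.

    Every buffered output is recomputed as ``phi(W z_in + b)`` from its
    stored pre-activation, so all cross-sample dependencies are retained.
    This is the unapproximated update the three-factor rule approximates;
    it serves as a validation oracle and is not itself local.
    """
    n = len(mem)
    if n < 2:
        raise ValueError("needs at least 2 buffered samples")
    a_in = np.stack(
        [
            mem[-p].z_in if mem[-p].z_in is not None else _missing(p)
            for p in range(n)
        ]
    )
    xs = mem.stack("x")
    ys = mem.stack("y")
    drive = a_in @ layer.W.T + layer.b
    phi, dphi = ACTIVATIONS[layer.activation]
    zs = phi(drive)
    m = (
        double_center(gram(xs, params.sigma_x))
        - params.gamma * double_center(gram(ys, params.sigma_y))
    ) / (n - 1) ** 2
    kz = gram(zs, params.sigma_z)
    s = m * kz
    # dL/dz_p = (-4/sigma^2) sum_q S_pq (z_p - z_q)
    c = (-4.0 / params.sigma_z**2) * (s.sum(axis=1)[:, None] * zs - s @ zs)
    gated = c * dphi(drive)
    return gated.T @ a_in, gated.sum(axis=0)


def _missing(p: int):
    raise ValueError(
        f"memory record at lag {-p} has no stored pre-activation z_in; "
        "push samples with z_in to use the exact-gradient oracle"
    )
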