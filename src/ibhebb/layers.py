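"""Forward models: leaky-integrate rate layers and instantaneous layers.

Two neuron models are supported.  The biological experiments use
rate-coded leaky-integrate neurons whose membrane potential relaxes toward
the synaptic drive,

    tau_m du/dt = -u + W z_in + b,        z = relu(u),

integrated by forward Euler; each input is held fixed for a presentation
window and the layer output is read at the window end.  The large-scale
experiments use instantaneous dense (and optionally convolutional) ReLU
layers, ``z = relu(W z_in + b)``, which are the infinite-presentation-time
limit of the rate model.

Every layer exposes the hooks the plasticity module needs: the current
post-synaptic drive (for the activation-derivative gate) and its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "LayerState",
    "NetworkSpec",
    "Network",
    "make_dense",
    "make_rate",
    "build_network",
    "dense_forward",
    "rate_step",
    "run_sample",
    "conv_forward",
    "avg_pool",
]


def _relu(u: np.ndarray) -> np.ndarray:
    return np.maximum(u, 0.0)


def _relu_grad(u: np.ndarray) -> np.ndarray:
    return (u > 0).astype(float)


# name -> (activation, derivative wrt drive)
ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "identity": (lambda u: u, lambda u: np.ones_like(u)),
    "tanh": (np.tanh, lambda u: 1.0 - np.tanh(u) ** 2),
}


@dataclass
class LayerState:
    """Parameters and state of one layer.

    ``kind`` is ``"rate"`` (leaky-integrate, membrane state ``u`` persists
    across samples), ``"dense"`` (instantaneous) or ``"conv"`` (3x3
    convolution, instantaneous).  For conv layers ``W`` has shape
    ``(out_ch, in_ch, 3, 3)`` and ``u`` is unused.
    """

    W: np.ndarray
    b: np.ndarray
    kind: str = "dense"
    activation: str = "relu"
    tau_m: float = 5.0
    u: np.ndarray | None = None
    # drive at the last forward evaluation; read by the plasticity gate
    last_drive: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("rate", "dense", "conv"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.kind == "rate":
            if self.tau_m <= 0:
                raise ValueError("tau_m must be positive")
            if self.u is None:
                self.u = np.zeros(self.W.shape[0])
        elif self.u is not None:
            raise ValueError("membrane state u only applies to rate layers")

    @property
    def out_dim(self) -> int:
        return self.W.shape[0]

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    def reset(self) -> None:
        """Zero the membrane state (rate layers only)."""
        if self.u is not None:
            self.u = np.zeros_like(self.u)


def _init_weights(out_dim: int, in_dim: int, rng: np.random.Generator) -> np.ndarray:
    # uniform in [-1/sqrt(fan_in), 1/sqrt(fan_in)]
    bound = 1.0 / np.sqrt(in_dim)
    return rng.uniform(-bound, bound, size=(out_dim, in_dim))


def _init_bias(out_dim: int, activation: str) -> np.ndarray:
    # small positive bias keeps ReLU units initially responsive; a unit
    # whose gate is closed everywhere receives no plasticity and can never
    # recover under a gated three-factor rule
    return np.full(out_dim, 0.1 if activation == "relu" else 0.0)


def make_dense(
    in_dim: int,
    out_dim: int,
    rng: np.random.Generator,
    activation: str = "relu",
) -> LayerState:
    return LayerState(
        W=_init_weights(out_dim, in_dim, rng),
        b=_init_bias(out_dim, activation),
        kind="dense",
        activation=activation,
    )


def make_rate(
    in_dim: int,
    out_dim: int,
    rng: np.random.Generator,
    tau_m: float = 5.0,
    activation: str = "relu",
) -> LayerState:
    return LayerState(
        W=_init_weights(out_dim, in_dim, rng),
        b=_init_bias(out_dim, activation),
        kind="rate",
        activation=activation,
        tau_m=tau_m,
    )


def dense_forward(layer: LayerState, z_in: np.ndarray) -> np.ndarray:
    """Instantaneous forward pass ``phi(W z_in + b)``."""
    if layer.kind == "conv":
        return conv_forward(layer, z_in)
    z_in = np.asarray(z_in, dtype=float)
    if z_in.shape[-1] != layer.in_dim:
        raise ValueError(
            f"input dim {z_in.shape[-1]} does not match layer in_dim {layer.in_dim}"
        )
    drive = layer.W @ z_in + layer.b
    layer.last_drive = drive
    phi, _ = ACTIVATIONS[layer.activation]
    return phi(drive)


def rate_step(layer: LayerState, z_in: np.ndarray, dt: float) -> np.ndarray:
    """One forward-Euler step of the leaky-integrate dynamics.

    ``u <- u + (dt/tau_m) (-u + W z_in + b)``; returns ``phi(u)``.
    """
    if layer.kind != "rate":
        raise ValueError("rate_step requires a rate layer")
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = layer.W @ np.asarray(z_in, dtype=float) + layer.b
    layer.u = layer.u + (dt / layer.tau_m) * (-layer.u + drive)
    if not np.all(np.isfinite(layer.u)):
        raise FloatingPointError("rate layer diverged (non-finite membrane potential)")
    layer.last_drive = layer.u
    phi, _ = ACTIVATIONS[layer.activation]
    return phi(layer.u)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: hidden sizes, neuron kind, output size.

    The final layer is a softmax readout trained against cross-entropy; the
    hidden layers are trained layer-wise by the bottleneck rule.
    """

    hidden_dims: tuple[int, ...]
    output_dim: int
    kind: str = "rate"  # rate | dense
    tau_m: float = 5.0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in ("rate", "dense"):
            raise ValueError(f"unsupported network kind {self.kind!r}")
        if any(d < 1 for d in self.hidden_dims) or self.output_dim < 1:
            raise ValueError("all layer widths must be >= 1")


@dataclass
class Network:
    """A stack of hidden layers plus a linear softmax readout."""

    hidden: list[LayerState]
    readout: LayerState
    spec: NetworkSpec

    @property
    def layers(self) -> list[LayerState]:
        return [*self.hidden, self.readout]

    def reset(self) -> None:
        for layer in self.layers:
            layer.reset()


def build_network(
    spec: NetworkSpec, input_dim: int, rng: np.random.Generator
) -> Network:
    """Instantiate a network from a spec with seeded initial weights."""
    dims = [input_dim, *spec.hidden_dims]
    hidden = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        if spec.kind == "rate":
            hidden.append(make_rate(d_in, d_out, rng, spec.tau_m, spec.activation))
        else:
            hidden.append(make_dense(d_in, d_out, rng, spec.activation))
    # readout is linear (softmax applied by the loss); rate readouts keep
    # membrane dynamics with an identity activation
    if spec.kind == "rate":
        readout = make_rate(dims[-1], spec.output_dim, rng, spec.tau_m, "identity")
    else:
        readout = make_dense(dims[-1], spec.output_dim, rng, "identity")
    return Network(hidden=hidden, readout=readout, spec=spec)


def run_sample(
    net: Network, x: np.ndarray, dt: float, dt_sample: float
) -> list[np.ndarray]:
    """Present one input and return every layer's output.

    Rate networks hold ``x`` fixed and step all layers synchronously in
    feedforward order every ``dt`` for ``dt_sample``; outputs are read at
    the window end.  Membrane state persists between calls.  Dense networks
    reduce to a single instantaneous pass.
    """
    x = np.asarray(x, dtype=float)
    if net.spec.kind == "dense":
        outs: list[np.ndarray] = []
        z = x
        for layer in net.layers:
            z = dense_forward(layer, z)
            outs.append(z)
        return outs
    if dt_sample < dt:
        raise ValueError("dt_sample must be at least dt")
    n_steps = int(round(dt_sample / dt))
    outs = [layer.u.copy() for layer in net.layers]  # placeholder
    for _ in range(n_steps):
        z = x
        zs = []
        for layer in net.layers:
            z = rate_step(layer, z, dt)
            zs.append(z)
        outs = zs
    return outs


# -- convolutional path (artificial networks only; not claimed plausible) --


def _im2col(x: np.ndarray, ksize: int = 3) -> np.ndarray:
    """(C, H, W) -> (H*W, C*ksize*ksize) patches with zero 'same' padding."""
    c, h, w = x.shape
    pad = ksize // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((h * w, c * ksize * ksize))
    idx = 0
    for i in range(h):
        for j in range(w):
            cols[idx] = xp[:, i : i + ksize, j : j + ksize].ravel()
            idx += 1
    return cols


def conv_forward(layer: LayerState, z_in: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution + activation on a (C, H, W) map."""
    if layer.kind != "conv":
        raise ValueError("conv_forward requires a conv layer")
    z_in = np.asarray(z_in, dtype=float)
    if z_in.ndim != 3:
        raise ValueError("conv input must be (channels, height, width)")
    out_ch, in_ch, kh, kw = layer.W.shape
    if z_in.shape[0] != in_ch:
        raise ValueError("channel mismatch")
    cols = _im2col(z_in, kh)  # (H*W, in_ch*kh*kw)
    drive = cols @ layer.W.reshape(out_ch, -1).T + layer.b  # (H*W, out_ch)
    h, w = z_in.shape[1:]
    drive = drive.T.reshape(out_ch, h, w)
    layer.last_drive = drive
    phi, _ = ACTIVATIONS[layer.activation]
    return phi(drive)


def avg_pool(z: np.ndarray, size: int = 2) -> np.ndarray:
    """Parameterless average pooling of a (C, H, W) map."""
    c, h, w = z.shape
    if h % size or w % size:
        raise ValueError("map size must be divisible by the pool size")
    return z.reshape(c, h // size, size, w // size, size).mean(axis=(2, 4))
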