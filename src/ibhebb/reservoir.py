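"""Auxiliary working-memory network: a rate reservoir with an LMS readout.

A fixed random recurrent population of leaky-integrate tanh neurons,

    tau_r du/dt = -u + lambda W_rr r + W_ir r_i + W_fb r_o,    r = tanh(u),

acts as a fading working memory of its input stream.  Only the linear
readout ``r_o = W_o r`` is trained, with the least-mean-squares FORCE rule

    W_o <- W_o - eta (r_o - xi) r^T,

against the true layer-wise modulation signal ``xi`` produced by
:func:`ibhebb.plasticity.modulation_signal`.  Because the target is a fixed
functional of the last ``N`` (input, label, activity) triples — not of any
particular dataset — the readout can be trained a priori and then frozen
while the primary network learns.

Initialisation follows echo-state conventions: sparse Gaussian recurrent
weights with per-entry variance ``1/(density * n_neurons)`` so the spectral
radius of ``lambda W_rr`` is approximately ``lambda``; input and feedback
weights uniform in [-1, 1]; readout weights zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReservoirParams",
    "ReservoirState",
    "EvalReport",
    "init_reservoir",
    "reservoir_step",
    "force_lms_update",
    "pretrain_reservoir",
    "evaluate_reservoir",
    "nrmse",
]


@dataclass(frozen=True)
class ReservoirParams:
    """Dynamics and learning hyper-parameters of the auxiliary network."""

    n_neurons: int = 2000
    tau_r: float = 5.0  # ms
    lambda_chaos: float = 1.2  # recurrent gain; >1 puts the autonomous net near chaos
    dt: float = 1.0  # ms
    dt_sample: float = 20.0  # ms each sample is held at the input
    connection_density: float = 0.1
    learn_rate: float = 5e-4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.dt <= 0 or self.dt > self.tau_r:
            raise ValueError("require 0 < dt <= tau_r")
        if self.lambda_chaos <= 0:
            raise ValueError("lambda_chaos must be positive")
        if not 0 < self.connection_density <= 1:
            raise ValueError("connection_density must be in (0, 1]")


@dataclass
class ReservoirState:
    """Membrane potentials, rates, readout and all weight matrices."""

    u: np.ndarray
    r: np.ndarray
    ro: np.ndarray
    W_rr: np.ndarray
    W_ir: np.ndarray
    W_fb: np.ndarray
    W_o: np.ndarray
    params: ReservoirParams = field(repr=False, default_factory=ReservoirParams)


def init_reservoir(
    params: ReservoirParams, input_dim: int, output_dim: int
) -> ReservoirState:
    """Seeded initial state; repeated calls are bitwise identical."""
    if input_dim < 1 or output_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(params.seed)
    n = params.n_neurons
    density = params.connection_density
    mask = rng.random((n, n)) < density
    w_rr = np.where(mask, rng.normal(0.0, 1.0 / np.sqrt(density * n), (n, n)), 0.0)
    w_ir = rng.uniform(-1.0, 1.0, (n, input_dim))
    w_fb = rng.uniform(-1.0, 1.0, (n, output_dim))
    u = 0.1 * rng.standard_normal(n)
    r = np.tanh(u)
    w_o = np.zeros((output_dim, n))
    return ReservoirState(
        u=u, r=r, ro=w_o @ r, W_rr=w_rr, W_ir=w_ir, W_fb=w_fb, W_o=w_o, params=params
    )


def reservoir_step(
    state: ReservoirState, r_i: np.ndarray, dt: float | None = None
) -> ReservoirState:
    """One forward-Euler step of the reservoir dynamics (in place).

    Feedback uses the previous step's readout; the readout is refreshed
    from the new rates afterwards, avoiding an algebraic loop.
    """
    p = state.params
    dt = p.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    drive = (
        p.lambda_chaos * (state.W_rr @ state.r)
        + state.W_ir @ np.asarray(r_i, dtype=float)
        + state.W_fb @ state.ro
    )
    state.u = state.u + (dt / p.tau_r) * (-state.u + drive)
    if not np.all(np.isfinite(state.u)):
        raise FloatingPointError("reservoir diverged (non-finite membrane potential)")
    state.r = np.tanh(state.u)
    state.ro = state.W_o @ state.r
    return state


def force_lms_update(
    state: ReservoirState, xi_true: np.ndarray, eta: float
) -> ReservoirState:
    """LMS FORCE step on the readout weights only (in place).

    ``W_o <- W_o - eta (ro - xi) r^T``; the recurrent, input and feedback
    weights are never modified.
    """
    xi_true = np.asarray(xi_true, dtype=float)
    if xi_true.shape != state.ro.shape:
        raise ValueError(
            f"target shape {xi_true.shape} does not match readout {state.ro.shape}"
        )
    err = state.ro - xi_true
    state.W_o = state.W_o - eta * np.outer(err, state.r)
    state.ro = state.W_o @ state.r
    return state


def _present(
    state: ReservoirState,
    r_i: np.ndarray,
    xi_true: np.ndarray | None,
    eta: float,
) -> None:
    """Hold one input for dt_sample, stepping each dt; learn if eta is set."""
    p = state.params
    n_steps = int(round(p.dt_sample / p.dt))
    for _ in range(n_steps):
        reservoir_step(state, r_i)
        if xi_true is not None:
            force_lms_update(state, xi_true, eta)


def pretrain_reservoir(
    state: ReservoirState,
    stream: Sequence[tuple[np.ndarray, np.ndarray | None]],
    epochs: int | None = None,
) -> ReservoirState:
    """Train the readout on a stream of (input, target) pairs.

    Each sample is held at the input for ``dt_sample`` ms; the readout
    error is evaluated after each dynamics step and the LMS update applied
    immediately.  Pairs with target ``None`` (warm-up before the oracle's
    buffer is populated) drive the dynamics without learning.
    """
    p = state.params
    epochs = p.epochs if epochs is None else epochs
    for _ in range(epochs):
        for r_i, xi_true in stream:
            _present(state, r_i, xi_true, p.learn_rate)
    return state


@dataclass(frozen=True)
class EvalReport:
    """Held-out evaluation: per-element and overall normalised RMSE."""

    nrmse_per_element: np.ndarray
    nrmse: float
    traces: pd.DataFrame  # columns: sample, element, target, prediction


def nrmse(pred: np.ndarray, target: np.ndarray) -> float:
    """RMSE normalised by the target's standard deviation.

    Defined as 0 when the target is constant and the error is zero (the
    degenerate case of a trivially matched constant signal).
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    rmse = float(np.sqrt(np.mean((pred - target) ** 2)))
    sd = float(np.std(target))
    if sd == 0.0:
        return 0.0 if rmse == 0.0 else float("inf")
    return rmse / sd


def evaluate_reservoir(
    state: ReservoirState,
    stream: Iterable[tuple[np.ndarray, np.ndarray | None]],
) -> EvalReport:
    """Run the dynamics with all weights frozen and score the readout.

    The prediction for each sample is the readout at the end of its
    presentation window; samples without a target (warm-up) still drive
    the dynamics but are excluded from scoring.
    """
    preds, targets, rows = [], [], []
    for s_idx, (r_i, xi_true) in enumerate(stream):
        _present(state, r_i, None, 0.0)
        if xi_true is None:
            continue
        preds.append(state.ro.copy())
        targets.append(np.asarray(xi_true, dtype=float))
        for e, (t, pr) in enumerate(zip(targets[-1], preds[-1])):
            rows.append(
                {"sample": s_idx, "element": e, "target": t, "prediction": pr}
            )
    pred = np.stack(preds)
    target = np.stack(targets)
    per_el = np.array(
        [nrmse(pred[:, j], target[:, j]) for j in range(target.shape[1])]
    )
    return EvalReport(
        nrmse_per_element=per_el,
        nrmse=nrmse(pred, target),
        traces=pd.DataFrame(rows),
    )


def save_reservoir(state: ReservoirState, path: str) -> None:
    """Serialise a trained reservoir to a single ``.npz`` archive."""
    np.savez_compressed(
        path,
        u=state.u,
        r=state.r,
        ro=state.ro,
        W_rr=state.W_rr,
        W_ir=state.W_ir,
        W_fb=state.W_fb,
        W_o=state.W_o,
        params=np.array(
            [
                state.params.n_neurons,
                state.params.tau_r,
                state.params.lambda_chaos,
                state.params.dt,
                state.params.dt_sample,
                state.params.connection_density,
                state.params.learn_rate,
                state.params.epochs,
                state.params.seed,
            ]
        ),
    )


def load_reservoir(path: str) -> ReservoirState:
    with np.load(path) as data:
        raw = data["params"]
        params = ReservoirParams(
            n_neurons=int(raw[0]),
            tau_r=float(raw[1]),
            lambda_chaos=float(raw[2]),
            dt=float(raw[3]),
            dt_sample=float(raw[4]),
            connection_density=float(raw[5]),
            learn_rate=float(raw[6]),
            epochs=int(raw[7]),
            seed=int(raw[8]),
        )
        return ReservoirState(
            u=data["u"],
            r=data["r"],
            ro=data["ro"],
            W_rr=data["W_rr"],
            W_ir=data["W_ir"],
            W_fb=data["W_fb"],
            W_o=data["W_o"],
            params=params,
        )
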