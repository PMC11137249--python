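"""Training orchestration: the per-sample loop, optimizers and experiments.

``train_hsic`` wires everything together.  Samples are presented one at a
time; each presentation runs the forward dynamics, pushes the (input,
label, layer output) triple into every hidden layer's working-memory
buffer, computes that layer's modulation signal (from the buffer directly,
or from a pre-trained auxiliary reservoir), and applies the three-factor
update.  The final layer is a softmax readout trained by the local
cross-entropy delta rule; no error ever propagates across layers.

A self-contained backpropagation baseline (``train_backprop``) is provided
for comparison on instantaneous networks, along with experiment runners
for the reservoir replication, the two synthetic tasks, the benchmark
protocol (opt-in, external data) and the memory-capacity sweep.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_synth import LabeledDataset, gen_linear, gen_reservoir_stream, gen_xor
from .hsic_core import KernelParams, hsic_objective
from .layers import ACTIVATIONS, Network, NetworkSpec, build_network, run_sample
from .plasticity import (
    SampleMemory,
    assemble_update,
    local_factor,
    modulation_signal,
)
from .reservoir import (
    ReservoirParams,
    ReservoirState,
    evaluate_reservoir,
    init_reservoir,
    pretrain_reservoir,
    reservoir_step,
)

__all__ = [
    "TrainConfig",
    "TrainReport",
    "SGD",
    "Adam",
    "adam_apply",
    "softmax",
    "output_layer_update",
    "train_hsic",
    "train_backprop",
    "run_experiment",
    "TABLE3",
]


def _table3_kernels() -> KernelParams:
    return KernelParams(sigma_x=0.3, sigma_z=2.0, sigma_y=0.25, gamma=10.0)


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of one training run.

    Defaults follow the published small-task protocol: 1 ms integration
    step, 5 ms membrane time constant, 20 ms presentation per sample,
    effective batch size 64, bandwidths (0.3, 2, 0.25), balance 10,
    learning rate 1e-4, 25 epochs.
    """

    dt: float = 1.0
    dt_sample: float = 20.0
    N: int = 64
    kernels: KernelParams = field(default_factory=_table3_kernels)
    eta: float = 1e-4
    eta_readout: float = 1e-2
    readout_decay: float = 0.0
    lr_schedule: str = "cosine"  # cosine | constant; hidden layers only
    anneal_frac: float = 0.5  # fraction of training over which the hidden rate decays to 0
    epochs: int = 25
    n_seeds: int = 1
    optimizer: str = "adam"  # sgd | adam
    xi_source: str = "oracle"  # oracle | reservoir
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("effective batch size N must be >= 2")
        if min(self.dt, self.dt_sample) <= 0 or self.epochs < 1:
            raise ValueError("dt and dt_sample must be positive and epochs >= 1")
        if self.eta < 0 or self.eta_readout < 0:
            raise ValueError("learning rates must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.xi_source not in ("oracle", "reservoir"):
            raise ValueError(f"unknown xi_source {self.xi_source!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.readout_decay < 0:
            raise ValueError("readout_decay must be >= 0")
        if not 0 < self.anneal_frac <= 1:
            raise ValueError("anneal_frac must be in (0, 1]")


# An alias for the default small-task configuration.
TABLE3 = TrainConfig()


@dataclass
class TrainReport:
    """Per-epoch metrics plus a config echo; fully seed-determined."""

    history: pd.DataFrame  # epoch, train_acc, test_acc, hsic_layer_0..L-1
    final_train_acc: float
    final_test_acc: float
    config: dict
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


# ------------------------------ optimizers ------------------------------


class SGD:
    """Plain stochastic gradient descent on supplied descent directions."""

    def __init__(self, eta: float):
        self.eta = eta

    def step(self, key: str, delta: np.ndarray) -> np.ndarray:
        return self.eta * delta


class Adam:
    """Adam with standard defaults (b1=0.9, b2=0.999, eps=1e-8).

    Keeps one moment pair per parameter key; ``step`` returns the amount
    to subtract from the parameter.
    """

    def __init__(self, eta: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.eta, self.b1, self.b2, self.eps = eta, b1, b2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, key: str, delta: np.ndarray) -> np.ndarray:
        delta = np.asarray(delta, dtype=float)
        m = self._m.get(key, np.zeros_like(delta))
        v = self._v.get(key, np.zeros_like(delta))
        t = self._t.get(key, 0) + 1
        m = self.b1 * m + (1 - self.b1) * delta
        v = self.b2 * v + (1 - self.b2) * delta**2
        self._m[key], self._v[key], self._t[key] = m, v, t
        m_hat = m / (1 - self.b1**t)
        v_hat = v / (1 - self.b2**t)
        return self.eta * m_hat / (np.sqrt(v_hat) + self.eps)


def adam_apply(
    state: Adam, key: str, param: np.ndarray, delta: np.ndarray
) -> np.ndarray:
    """Apply one Adam step to ``param`` for descent direction ``delta``."""
    return param - state.step(key, delta)


def _make_optimizer(cfg: TrainConfig, eta: float | None = None) -> SGD | Adam:
    eta = cfg.eta if eta is None else eta
    return Adam(eta) if cfg.optimizer == "adam" else SGD(eta)


# ------------------------- readout and metrics --------------------------


def softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - np.max(v))
    return e / e.sum()


def output_layer_update(
    layer, z_in: np.ndarray, y_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Local cross-entropy delta rule for the softmax readout.

    ``dW = (softmax(drive) - y) z_in^T`` — the exact cross-entropy
    gradient of the final layer alone, requiring only that layer's input
    and the label.  Returned as a descent direction.
    """
    y_true = np.asarray(y_true, dtype=float)
    drive = layer.u if layer.kind == "rate" else layer.W @ z_in + layer.b
    err = softmax(drive) - y_true
    if err.shape != y_true.shape:
        raise ValueError("label dimension does not match readout")
    return np.outer(err, z_in), err


def _forward_fresh(net: Network, x: np.ndarray, cfg: TrainConfig) -> list[np.ndarray]:
    """Forward pass from a rested membrane state (evaluation only)."""
    net.reset()
    return run_sample(net, x, cfg.dt, cfg.dt_sample)


def accuracy(net: Network, data: LabeledDataset, idx: np.ndarray, cfg: TrainConfig) -> float:
    """Fraction of samples whose readout argmax matches the label."""
    hits = 0
    for i in idx:
        out = _forward_fresh(net, data.X[i], cfg)[-1]
        hits += int(np.argmax(out) == data.labels[i])
    return hits / len(idx)


def _layer_hsic(
    net: Network, data: LabeledDataset, idx: np.ndarray, cfg: TrainConfig
) -> list[float]:
    """Trace-form bottleneck objective of each hidden layer on a subset."""
    zs = {l: [] for l in range(len(net.hidden))}
    for i in idx:
        outs = _forward_fresh(net, data.X[i], cfg)
        for l in range(len(net.hidden)):
            zs[l].append(outs[l])
    return [
        hsic_objective(data.X[idx], data.y[idx], np.stack(zs[l]), cfg.kernels)
        for l in range(len(net.hidden))
    ]


# ----------------------------- training loops ---------------------------


def _xi_from_reservoir(
    res: ReservoirState, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Drive a frozen reservoir with [x; y; z] for one window, read xi."""
    r_i = np.concatenate([x, y, z])
    n_steps = int(round(res.params.dt_sample / res.params.dt))
    for _ in range(n_steps):
        reservoir_step(res, r_i)
    return res.ro.copy()


def train_hsic(
    net: Network,
    data: LabeledDataset,
    cfg: TrainConfig,
    reservoirs: list[ReservoirState] | None = None,
    eval_subset: int = 200,
) -> TrainReport:
    """Train hidden layers with the three-factor rule, readout with CE.

    ``reservoirs`` supplies one pre-trained auxiliary network per hidden
    layer when ``cfg.xi_source == "reservoir"``; with the default
    ``"oracle"`` source the modulation signal is computed exactly from the
    buffer.  Updates are skipped until a layer's buffer holds two samples.
    """
    if cfg.xi_source == "reservoir":
        if reservoirs is None or len(reservoirs) != len(net.hidden):
            raise ValueError("xi_source='reservoir' needs one reservoir per hidden layer")
    rng = np.random.default_rng(cfg.seed)
    opt = _make_optimizer(cfg)
    opt_ro = _make_optimizer(cfg, cfg.eta_readout)
    mems = [SampleMemory(cfg.N) for _ in net.hidden]
    hsic_idx = data.train_idx[: min(eval_subset, len(data.train_idx))]
    rows = []

    def record(epoch: int) -> dict:
        row = {
            "epoch": epoch,
            "train_acc": accuracy(net, data, data.train_idx, cfg),
            "test_acc": accuracy(net, data, data.test_idx, cfg),
        }
        for l, v in enumerate(_layer_hsic(net, data, hsic_idx, cfg)):
            row[f"hsic_layer_{l}"] = v
        return row

    rows.append(record(0))
    n_total = cfg.epochs * len(data.train_idx)
    t = 0
    for epoch in range(1, cfg.epochs + 1):
        net.reset()
        order = rng.permutation(data.train_idx)
        for i in order:
            x, y = data.X[i], data.y[i]
            # hidden learning-rate schedule: anneal to zero so the
            # representation settles once the kernels saturate
            if cfg.lr_schedule == "cosine":
                frac = min(t / (cfg.anneal_frac * n_total), 1.0)
                scale = 0.5 * (1.0 + np.cos(np.pi * frac))
            else:
                scale = 1.0
            t += 1
            outs = run_sample(net, x, cfg.dt, cfg.dt_sample)
            z_ins = [x, *outs[:-1]]
            for l, layer in enumerate(net.hidden):
                mems[l].push(x, y, outs[l], z_in=z_ins[l])
                if len(mems[l]) < 2:
                    continue
                if cfg.xi_source == "oracle":
                    xi = modulation_signal(mems[l], cfg.kernels)
                    xi_vec = xi.xi
                else:
                    xi_vec = _xi_from_reservoir(reservoirs[l], x, y, outs[l])
                beta = local_factor(layer, z_ins[l])
                d_w, d_b = assemble_update(beta, _as_signal(xi_vec))
                layer.W = layer.W - scale * opt.step(f"h{l}.W", d_w)
                layer.b = layer.b - scale * opt.step(f"h{l}.b", d_b)
            d_w, d_b = output_layer_update(net.readout, z_ins[-1], y)
            # decoupled weight decay bounds the readout's confidence so it
            # can keep tracking the moving hidden representation
            decay = cfg.eta_readout * cfg.readout_decay
            net.readout.W = (1.0 - decay) * net.readout.W - opt_ro.step("out.W", d_w)
            net.readout.b = net.readout.b - opt_ro.step("out.b", d_b)
            if not all(np.all(np.isfinite(layer.W)) for layer in net.layers):
                raise FloatingPointError(f"weights diverged at epoch {epoch}")
        rows.append(record(epoch))
    history = pd.DataFrame(rows)
    return TrainReport(
        history=history,
        final_train_acc=float(history["train_acc"].iloc[-1]),
        final_test_acc=float(history["test_acc"].iloc[-1]),
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
    )


def _as_signal(xi_vec: np.ndarray):
    from .plasticity import ModulationSignal

    return ModulationSignal(xi=np.asarray(xi_vec, dtype=float))


# ----------------------- backpropagation baseline -----------------------


def backprop_gradients(
    net: Network, x: np.ndarray, y: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """End-to-end cross-entropy gradients for an instantaneous network."""
    if net.spec.kind != "dense":
        raise ValueError("the backprop baseline supports dense networks only")
    acts = [np.asarray(x, dtype=float)]
    drives = []
    for layer in net.layers:
        drive = layer.W @ acts[-1] + layer.b
        drives.append(drive)
        phi, _ = ACTIVATIONS[layer.activation]
        acts.append(phi(drive))
    delta = softmax(drives[-1]) - y  # identity readout activation
    grads: list[tuple[np.ndarray, np.ndarray]] = []
    for l in range(len(net.layers) - 1, -1, -1):
        grads.append((np.outer(delta, acts[l]), delta.copy()))
        if l > 0:
            _, dphi = ACTIVATIONS[net.layers[l - 1].activation]
            delta = (net.layers[l].W.T @ delta) * dphi(drives[l - 1])
    grads.reverse()
    return grads


def train_backprop(net: Network, data: LabeledDataset, cfg: TrainConfig) -> TrainReport:
    """Per-sample end-to-end baseline with the same reporting as train_hsic."""
    rng = np.random.default_rng(cfg.seed)
    opt = _make_optimizer(cfg)
    rows = []

    def record(epoch: int) -> dict:
        return {
            "epoch": epoch,
            "train_acc": accuracy(net, data, data.train_idx, cfg),
            "test_acc": accuracy(net, data, data.test_idx, cfg),
        }

    rows.append(record(0))
    for epoch in range(1, cfg.epochs + 1):
        for i in rng.permutation(data.train_idx):
            grads = backprop_gradients(net, data.X[i], data.y[i])
            for l, (layer, (d_w, d_b)) in enumerate(zip(net.layers, grads)):
                layer.W = layer.W - opt.step(f"l{l}.W", d_w)
                layer.b = layer.b - opt.step(f"l{l}.b", d_b)
        rows.append(record(epoch))
    history = pd.DataFrame(rows)
    return TrainReport(
        history=history,
        final_train_acc=float(history["train_acc"].iloc[-1]),
        final_test_acc=float(history["test_acc"].iloc[-1]),
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
    )


# ----------------------------- experiments ------------------------------


def _plot_history(histories: list[pd.DataFrame], labels: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for h, lab in zip(histories, labels):
        ax.plot(h["epoch"], h["test_acc"], label=lab)
    ax.set_xlabel("epoch")
    ax.set_ylabel("test accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def experiment_reservoir(
    out_dir: Path,
    n_neurons: int = 500,
    n_train: int = 100,
    n_test: int = 100,
    seed: int = 0,
) -> dict:
    """Scaled replication of the reservoir pre-training study.

    A reservoir is trained with the LMS FORCE rule to reproduce the exact
    modulation signal on a random stream, then scored on a held-out stream
    with all weights frozen.  Published dynamics/learning settings: tau_r
    5 ms, lambda 1.2, dt 1 ms, 20 ms per sample, N = 10, gamma = 2,
    sigma = 0.5, eta = 5e-4, 10 epochs.
    """
    params = ReservoirParams(n_neurons=n_neurons, seed=seed)
    kp = KernelParams(sigma_x=0.5, sigma_z=0.5, sigma_y=0.5, gamma=2.0)
    # stream dimensions scaled down with the population size; the published
    # run pairs 2000 neurons with image inputs and a 10-element activity
    z_dim, input_dim, n_classes = 3, 6, 5
    train = gen_reservoir_stream(
        n_samples=n_train, input_dim=input_dim, z_dim=z_dim, n_classes=n_classes,
        N=10, params=kp, seed=seed,
    )
    test = gen_reservoir_stream(
        n_samples=n_test, input_dim=input_dim, z_dim=z_dim, n_classes=n_classes,
        N=10, params=kp, seed=seed + 10_000,
    )
    state = init_reservoir(params, input_dim + n_classes + z_dim, z_dim)
    pretrain_reservoir(state, train)
    report = evaluate_reservoir(state, test)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.traces.to_csv(out_dir / "reservoir_traces.csv", index=False)
    summary = {
        "nrmse": report.nrmse,
        "nrmse_per_element": report.nrmse_per_element.tolist(),
        "n_neurons": n_neurons,
        "seed": seed,
    }
    (out_dir / "reservoir_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def experiment_synthetic(
    out_dir: Path,
    task: str = "both",
    n: int = 1000,
    n_test: int = 100,
    epochs: int = 25,
    n_seeds: int = 3,
    seed: int = 0,
) -> dict:
    """The two small-task studies: linear (1 hidden layer of 4 rate
    neurons) and noisy XOR (hidden layers of 10 and 4)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tasks = ("linear", "xor") if task == "both" else (task,)
    for name in tasks:
        accs, hists = [], []
        hsic_drop_all = []
        for s in range(n_seeds):
            run_seed = seed + s
            cfg = TrainConfig(epochs=epochs, seed=run_seed)
            if name == "linear":
                data = gen_linear(n=n, n_test=n_test, seed=run_seed)
                spec = NetworkSpec(hidden_dims=(4,), output_dim=2, kind="rate")
            else:
                data = gen_xor(n=n, n_test=n_test, seed=run_seed)
                spec = NetworkSpec(hidden_dims=(10, 4), output_dim=2, kind="rate")
            net = build_network(spec, 2, np.random.default_rng(run_seed))
            report = train_hsic(net, data, cfg)
            report.history.to_csv(out_dir / f"{name}_seed{run_seed}.csv", index=False)
            accs.append(report.final_test_acc)
            hists.append(report.history)
            h_cols = [c for c in report.history.columns if c.startswith("hsic_")]
            hsic_drop_all.append(
                [
                    float(report.history[c].iloc[-1] - report.history[c].iloc[0])
                    for c in h_cols
                ]
            )
        results[name] = {
            "mean_final_test_acc": float(np.mean(accs)),
            "per_seed_test_acc": [float(a) for a in accs],
            "hsic_change_per_layer": hsic_drop_all,
        }
        _plot_history(hists, [f"seed {seed + s}" for s in range(n_seeds)],
                      out_dir / f"{name}_accuracy.png")
    (out_dir / "synthetic_summary.json").write_text(json.dumps(results, indent=2))
    return results


def experiment_batchsweep(
    out_dir: Path,
    sizes: tuple[int, ...] = (2, 4, 8, 16),
    n_seeds: int = 5,
    n: int = 400,
    n_test: int = 80,
    epochs: int = 10,
    seed: int = 0,
) -> dict:
    """Memory-capacity sweep: final train accuracy vs effective batch size.

    Run at reduced scale on the XOR task; the published finding is a
    logarithmic improvement with capacity.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for N in sizes:
        for s in range(n_seeds):
            run_seed = seed + s
            cfg = TrainConfig(N=N, epochs=epochs, seed=run_seed)
            data = gen_xor(n=n, n_test=n_test, seed=run_seed)
            spec = NetworkSpec(hidden_dims=(10, 4), output_dim=2, kind="rate")
            net = build_network(spec, 2, np.random.default_rng(run_seed))
            report = train_hsic(net, data, cfg)
            rows.append(
                {"N": N, "seed": run_seed, "final_train_acc": report.final_train_acc,
                 "final_test_acc": report.final_test_acc}
            )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "batchsweep.csv", index=False)
    agg = df.groupby("N")["final_train_acc"].agg(["mean", "sem"]).reset_index()
    agg["sem"] = agg["sem"].fillna(0.0)
    summary = {
        "sizes": list(sizes),
        "mean_final_train_acc": agg["mean"].tolist(),
        "sem_final_train_acc": agg["sem"].tolist(),
    }
    (out_dir / "batchsweep_summary.json").write_text(json.dumps(summary, indent=2))
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(agg["N"], agg["mean"], yerr=agg["sem"], marker="o")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("effective batch size N")
    ax.set_ylabel("final train accuracy")
    fig.tight_layout()
    fig.savefig(out_dir / "batchsweep.png", dpi=120)
    plt.close(fig)
    return summary


def experiment_benchmarks(out_dir: Path, data_root: str, seed: int = 0) -> dict:
    """Opt-in MNIST protocol (external data required): MLP 128-64-10,
    three-factor rule vs backprop baseline, instantaneous ReLU layers."""
    from .data_synth import load_benchmark

    data = load_benchmark("mnist", data_root)
    out_dir.mkdir(parents=True, exist_ok=True)
    kp = KernelParams(sigma_x=0.5, sigma_z=1.0, sigma_y=0.1, gamma=2.0)
    cfg = TrainConfig(N=8, kernels=kp, eta=1e-4, epochs=25, seed=seed, optimizer="adam")
    spec = NetworkSpec(hidden_dims=(128, 64), output_dim=10, kind="dense")
    net = build_network(spec, data.X.shape[1], np.random.default_rng(seed))
    report = train_hsic(net, data, cfg)
    cfg_bp = dataclasses.replace(cfg, eta=1e-3)
    net_bp = build_network(spec, data.X.shape[1], np.random.default_rng(seed))
    report_bp = train_backprop(net_bp, data, cfg_bp)
    report.to_csv(out_dir / "mnist_hsic.csv")
    report_bp.to_csv(out_dir / "mnist_backprop.csv")
    summary = {
        "hsic_final_test_acc": report.final_test_acc,
        "backprop_final_test_acc": report_bp.final_test_acc,
    }
    (out_dir / "mnist_summary.json").write_text(json.dumps(summary, indent=2))
    return summary


_EXPERIMENTS = {
    "fig3_reservoir": lambda out, seed, **kw: experiment_reservoir(out, seed=seed, **kw),
    "fig4_synthetic": lambda out, seed, **kw: experiment_synthetic(out, seed=seed, **kw),
    "fig6_batchsweep": lambda out, seed, **kw: experiment_batchsweep(out, seed=seed, **kw),
}


def run_experiment(name: str, out_dir: str | Path, seed: int = 0, **kwargs) -> dict:
    """Dispatch an experiment by name; writes CSV/JSON/PNG under out_dir."""
    out_dir = Path(out_dir)
    if name == "fig5_benchmarks":
        data_root = kwargs.pop("data_root", None)
        if data_root is None:
            raise ValueError("fig5_benchmarks needs data_root pointing at local MNIST")
        return experiment_benchmarks(out_dir, data_root, seed=seed)
    if name not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}")
    return _EXPERIMENTS[name](out_dir, seed, **kwargs)
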