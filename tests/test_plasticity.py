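"""Working-memory buffer, modulation signal and the three-factor update.

The central correctness claims: (i) the exact-gradient oracle matches
finite differences of the trace-form objective; (ii) the assembled
three-factor update is exactly the gradient of the diagonal surrogate with
the stored past outputs frozen — the locality approximation that makes the
rule Hebbian.
"""

import numpy as np
import pytest

from ibhebb.hsic_core import (
    KernelParams,
    hsic_diag_objective,
    hsic_objective,
)
from ibhebb.layers import LayerState
from ibhebb.plasticity import (
    SampleMemory,
    alpha,
    assemble_update,
    full_hsic_gradient,
    local_factor,
    memory_push,
    modulation_signal,
)

KP = KernelParams(sigma_x=0.6, sigma_z=0.8, sigma_y=0.7, gamma=1.7)


def _fill_memory(rng, n=6, din=4, dout=3, activation="tanh", layer=None):
    """Push n random samples through a small dense layer into a buffer."""
    if layer is None:
        layer = LayerState(
            W=rng.normal(0, 0.7, (dout, din)),
            b=rng.normal(0, 0.3, dout),
            kind="dense",
            activation=activation,
        )
    mem = SampleMemory(n)
    phi = {"tanh": np.tanh, "identity": lambda u: u,
           "relu": lambda u: np.maximum(u, 0)}[activation]
    for _ in range(n):
        a = rng.uniform(0, 1, layer.in_dim)
        x = rng.uniform(0, 1, 2)
        y = rng.uniform(0, 1, 2)
        mem.push(x, y, phi(layer.W @ a + layer.b), z_in=a)
    return mem, layer


class TestSampleMemory:
    def test_push_and_capacity(self):
        mem = SampleMemory(3)
        assert len(mem) == 0
        for k in range(4):
            mem.push([float(k)], [0.0], [0.0])
        assert len(mem) == 3
        # oldest (k=0) evicted; index -p reaches p steps back
        assert mem[0].x[0] == 3.0
        assert mem[-1].x[0] == 2.0
        assert mem[-2].x[0] == 1.0

    def test_dimension_mismatch_rejected(self):
        mem = SampleMemory(2)
        mem.push([0.0, 1.0], [1.0], [0.5])
        with pytest.raises(ValueError):
            memory_push(mem, [0.0], [1.0], [0.5])

    def test_capacity_below_two_rejected(self):
        with pytest.raises(ValueError):
            SampleMemory(1)

    def test_frame_roundtrip(self):
        mem = SampleMemory(2)
        mem.push([0.1], [1.0, 0.0], [0.3, 0.4])
        mem.push([0.2], [0.0, 1.0], [0.5, 0.6])
        df = mem.to_frame()
        assert list(df["lag"]) == [0, -1]
        assert df.loc[0, "x0"] == 0.2


class TestAlpha:
    def test_identical_outputs_give_zero(self):
        z = np.array([0.3, 0.7])
        assert np.allclose(alpha(z, z, 1.0), 0.0)

    def test_hand_value(self):
        out = alpha(np.array([1.0, 0.0]), np.zeros(2), 1.0)
        assert np.allclose(out, [np.exp(-1), 0.0])

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert np.allclose(alpha(a, b, 0.9), -alpha(b, a, 0.9))


class TestModulationSignal:
    def test_constant_memory_gives_zero(self):
        mem = SampleMemory(4)
        for _ in range(4):
            mem.push([0.2, 0.8], [1.0, 0.0], [0.5, 0.5, 0.5])
        assert np.allclose(modulation_signal(mem, KP).xi, 0.0)

    def test_hand_expansion_n2(self):
        # scalar entries; expand the formula fully by hand
        sx, sz, sy, g = 0.5, 1.5, 0.7, 2.0
        params = KernelParams(sx, sz, sy, g)
        mem = SampleMemory(2)
        x = [0.0, 1.0]
        y = [0.0, 0.5]
        z = [0.2, 0.9]
        mem.push([x[0]], [y[0]], [z[0]])
        mem.push([x[1]], [y[1]], [z[1]])  # index 0 = current
        kx = np.exp(-((x[1] - x[0]) ** 2) / sx**2)
        ky = np.exp(-((y[1] - y[0]) ** 2) / sy**2)
        kz = np.exp(-((z[1] - z[0]) ** 2) / sz**2)
        s_x = 1 - (1 + kx) / 2  # same for both entries when N = 2
        s_y = 1 - (1 + ky) / 2
        w = s_x - g * s_y
        a = kz * (z[1] - z[0])
        expected = (2.0 / (sz**2 * 2 * 1**2)) * (w * a + a * w)
        assert modulation_signal(mem, params).xi[0] == pytest.approx(expected, rel=1e-12)

    def test_requires_two_entries(self):
        mem = SampleMemory(3)
        mem.push([0.1], [1.0], [0.2])
        with pytest.raises(ValueError):
            modulation_signal(mem, KP)

    def test_invariant_under_history_reordering(self, rng):
        # the sums over past lags are permutation symmetric
        xs = rng.uniform(0, 1, (5, 2))
        ys = rng.uniform(0, 1, (5, 2))
        zs = rng.uniform(0, 1, (5, 3))
        def build(order):
            mem = SampleMemory(5)
            for i in order:
                mem.push(xs[i], ys[i], zs[i])
            mem.push(xs[4], ys[4], zs[4])
            return modulation_signal(mem, KP).xi
        base = build([0, 1, 2, 3])
        shuffled = build([2, 0, 3, 1])
        assert np.allclose(base, shuffled, atol=1e-14)


class TestLocalFactor:
    def test_dead_relu_gates_zero(self):
        layer = LayerState(W=-np.ones((3, 2)), b=np.zeros(3), kind="dense")
        beta = local_factor(layer, np.array([0.5, 0.5]))
        assert np.all(beta.post_gate == 0.0)
        delta_w, delta_b = assemble_update(beta, _sig(np.ones(3)))
        assert np.allclose(delta_w, 0.0) and np.allclose(delta_b, 0.0)

    def test_identity_gates_one(self, rng):
        layer = LayerState(
            W=rng.normal(size=(3, 2)), b=np.zeros(3), kind="dense", activation="identity"
        )
        beta = local_factor(layer, rng.normal(size=2))
        assert np.all(beta.post_gate == 1.0)

    def test_relu_gates_match_drive_sign(self, rng):
        layer = LayerState(W=rng.normal(size=(2, 2)), b=rng.normal(size=2), kind="dense")
        z_in = rng.uniform(0, 1, 2)
        beta = local_factor(layer, z_in)
        assert np.array_equal(beta.post_gate, (layer.W @ z_in + layer.b > 0).astype(float))

    def test_unknown_layer_kind_rejected(self):
        layer = LayerState(W=np.ones((1, 1, 3, 3)), b=np.zeros(1), kind="conv")
        with pytest.raises(ValueError):
            local_factor(layer, np.zeros((1, 2, 2)))


def _sig(v):
    from ibhebb.plasticity import ModulationSignal

    return ModulationSignal(xi=np.asarray(v, dtype=float))


class TestAssembleUpdate:
    def test_zero_xi_gives_zero(self, rng):
        from ibhebb.plasticity import LocalFactor

        beta = LocalFactor(post_gate=np.ones(3), pre_activity=rng.normal(size=4))
        dw, db = assemble_update(beta, _sig(np.zeros(3)))
        assert np.allclose(dw, 0.0) and np.allclose(db, 0.0)

    def test_rank_one_structure(self, rng):
        from ibhebb.plasticity import LocalFactor

        gate = rng.integers(0, 2, 4).astype(float)
        pre = rng.normal(size=5)
        xi = rng.normal(size=4)
        dw, db = assemble_update(LocalFactor(gate, pre), _sig(xi))
        assert np.allclose(dw, np.outer(xi * gate, pre))
        assert np.linalg.matrix_rank(dw) <= 1

    def test_locality_pure_function(self):
        # depends only on (gate, pre-activity, xi): identical inputs, identical output
        from ibhebb.plasticity import LocalFactor

        beta = LocalFactor(np.array([1.0, 0.0]), np.array([0.2, 0.4, 0.6]))
        a = assemble_update(beta, _sig([0.5, -0.5]))
        b = assemble_update(beta, _sig([0.5, -0.5]))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestGradients:
    """Finite-difference verification of both gradient routes."""

    def _fd(self, f, theta, eps=1e-6):
        g = np.zeros_like(theta)
        it = np.nditer(theta, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            g[i] = (f(tp) - f(tm)) / (2 * eps)
        return g

    def test_full_gradient_matches_trace_objective_fd(self, rng):
        mem, layer = _fill_memory(rng)
        xs, ys = mem.stack("x"), mem.stack("y")
        a_in = np.stack([mem[-p].z_in for p in range(len(mem))])

        def obj_w(w):
            return hsic_objective(xs, ys, np.tanh(a_in @ w.T + layer.b), KP)

        def obj_b(b):
            return hsic_objective(xs, ys, np.tanh(a_in @ layer.W.T + b), KP)

        gw, gb = full_hsic_gradient(mem, layer, KP)
        num_w = self._fd(obj_w, layer.W)
        num_b = self._fd(obj_b, layer.b)
        assert np.max(np.abs(gw - num_w)) / np.max(np.abs(num_w)) < 1e-4
        assert np.max(np.abs(gb - num_b)) / np.max(np.abs(num_b)) < 1e-4

    def test_three_factor_equals_frozen_past_gradient(self, rng):
        # restricted oracle: diagonal surrogate, past outputs frozen,
        # current output recomputed from the perturbed weights
        mem, layer = _fill_memory(rng)
        xs, ys, zs = mem.stack("x"), mem.stack("y"), mem.stack("z")
        a0 = mem[0].z_in

        def obj_w(w):
            z = zs.copy()
            z[0] = np.tanh(w @ a0 + layer.b)
            return hsic_diag_objective(xs, ys, z, KP)

        xi = modulation_signal(mem, KP)
        beta = local_factor(layer, a0)
        dw, _ = assemble_update(beta, xi)
        num = self._fd(obj_w, layer.W)
        assert np.max(np.abs(dw - num)) / np.max(np.abs(num)) < 1e-5

    def test_constant_representation_gives_zero_gradients(self, rng):
        # dead ReLU layer: output constant in theta -> both routes vanish
        layer = LayerState(
            W=np.zeros((3, 4)), b=np.full(3, -1.0), kind="dense", activation="relu"
        )
        mem = SampleMemory(4)
        for _ in range(4):
            a = rng.uniform(0, 1, 4)
            mem.push(rng.uniform(0, 1, 2), rng.uniform(0, 1, 2),
                     np.maximum(layer.W @ a + layer.b, 0), z_in=a)
        gw, gb = full_hsic_gradient(mem, layer, KP)
        assert np.allclose(gw, 0.0) and np.allclose(gb, 0.0)
        dw, db = assemble_update(
            local_factor(layer, mem[0].z_in), modulation_signal(mem, KP)
        )
        assert np.allclose(dw, 0.0) and np.allclose(db, 0.0)

    def test_full_gradient_collapses_when_history_is_current(self, rng):
        # replaying the current pre-activation into every slot makes all
        # outputs identical, so both the exact gradient and the assembled
        # update vanish together
        layer = LayerState(
            W=rng.normal(0, 0.7, (3, 4)), b=rng.normal(0, 0.3, 3),
            kind="dense", activation="tanh",
        )
        a0 = rng.uniform(0, 1, 4)
        z0 = np.tanh(layer.W @ a0 + layer.b)
        mem = SampleMemory(4)
        for _ in range(4):
            mem.push(rng.uniform(0, 1, 2), rng.uniform(0, 1, 2), z0, z_in=a0)
        gw, gb = full_hsic_gradient(mem, layer, KP)
        dw, db = assemble_update(
            local_factor(layer, a0), modulation_signal(mem, KP)
        )
        assert np.allclose(dw, gw, atol=1e-12)
        assert np.allclose(db, gb, atol=1e-12)
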